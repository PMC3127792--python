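"""Synthetic-data generator emulating a soybean RIL mapping design.

The generator is the test bed for the whole package. Its defaults mirror
the design it emulates: 184 recombinant inbred lines genotyped at 950
markers in 25 linkage groups, phenotyped for leaf, stem and root biomass
at six times between day 20 and day 120 after emergence, with one QTL
whose two homozygous genotypes follow distinct allometric growth
systems. Residual noise is i.i.d. Gaussian ("white") per trait and time,
with variances either given explicitly or scaled so that each trait's
heritability at the middle measurement time matches a target (the
default 0.05 is a deliberately hard setting: 95% of the mid-season
phenotypic variance is noise).

RIL genomes are drawn marker-by-marker along each group as a two-state
Markov chain whose transition probability is the selfed-RIL-expanded
recombination fraction of the adjacent-marker interval; unlinked groups
are independent. Default generating parameter pairs are point estimates
from a published soybean biomass-partitioning analysis of this design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    CODE_P1, CODE_P2, GenotypeMatrix, LinkageGroup, LinkageMap,
    _MAP_FUNCTIONS, locate, qtl_genotype_probs, ril_expansion,
)
from .io import PhenotypePanel, TraitSeries
from .trait_ode import OdeParams, solve_trajectory

# Generating parameter sets for the default two-genotype QTL
# (alpha_L, beta_L, gamma_L, alpha_S, beta_S, alpha_R, beta_R, gamma_R).
GENOTYPE1_PARAMS = OdeParams(2.55, 0.10, 0.31, 0.98, 0.04, 1.11, 0.51, 2.18)
GENOTYPE2_PARAMS = OdeParams(1.89, 0.14, 0.44, 1.04, 0.07, 1.11, 0.56, 1.85)
# One-curve (no-QTL) generating set for null / false-positive studies.
NULL_PARAMS = OdeParams(2.25, 0.12, 0.37, 1.03, 0.05, 1.12, 0.55, 2.06)

DEFAULT_TIMES = np.linspace(20.0, 120.0, 6)


def default_linkage_map(n_groups: int = 25, markers_per_group: int = 38,
                        spacing_cm: float = 2.5) -> LinkageMap:
    """An evenly spaced map with the default 25 x 38 = 950 markers."""
    groups = []
    for g in range(n_groups):
        names = tuple(f"m{g + 1:02d}_{k + 1:02d}" for k in range(markers_per_group))
        pos = np.arange(markers_per_group) * spacing_cm
        groups.append(LinkageGroup(f"g{g + 1:02d}", names, pos))
    return LinkageMap(tuple(groups))


def small_linkage_map(n_markers: int = 7, spacing_cm: float = 10.0,
                      name: str = "g01") -> LinkageMap:
    """A single-group map for desk-scale scans and power studies."""
    names = tuple(f"m{k + 1:02d}" for k in range(n_markers))
    return LinkageMap((LinkageGroup(name, names, np.arange(n_markers) * spacing_cm),))


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the generator (defaults = emulated design)."""

    seed: int
    n_rils: int = 184
    linkage_map: LinkageMap = field(default_factory=default_linkage_map)
    generation: int = 7
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    qtl_group: str | None = None     # default: group of the middle marker
    qtl_cm: float | None = None      # default: a central marker position
    h2: float = 0.05
    sigma: np.ndarray | None = None  # explicit per-trait residual SDs override h2
    mapfun: str = "haldane"
    dropout: float = 0.0             # MCAR per-(line, time) removal probability

    def __post_init__(self):
        if self.n_rils < 2:
            raise ValueError("need at least two RILs")
        if self.sigma is None and not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def resolved_qtl(self) -> tuple[str, float]:
        g = self.qtl_group or self.linkage_map.groups[0].name
        group = self.linkage_map.group(g)
        cm = self.qtl_cm if self.qtl_cm is not None else float(
            group.positions[len(group.positions) // 2]
        )
        return g, cm


@dataclass
class SimDataset:
    """Simulated genotypes + phenotypes with a full truth record."""

    linkage_map: LinkageMap
    genotypes: GenotypeMatrix
    panel: PhenotypePanel
    truth: dict

    def omega_at_truth(self, mapfun: str = "haldane") -> np.ndarray:
        qtl = locate(self.linkage_map, self.truth["qtl_group"], self.truth["qtl_cm"])
        return qtl_genotype_probs(self.genotypes, self.linkage_map, qtl, mapfun=mapfun)


def simulate_ril_genomes(
    linkage_map: LinkageMap,
    n: int,
    generation: int = 7,
    seed: int | np.random.Generator = 0,
    mapfun: str = "haldane",
) -> GenotypeMatrix:
    """Draw fully homozygous RIL genomes marker-by-marker.

    Within a group the parental origin follows a two-state Markov chain:
    the first marker is a fair coin and each subsequent marker switches
    with the RIL-expanded recombination fraction of its interval. Groups
    segregate independently. ``generation`` is recorded for the design
    (F7 lines are >98% fixed); genomes are drawn at the fully inbred
    limit, whose expansion is R = 2r/(1+2r).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if generation < 2:
        raise ValueError("selfing generations start at F2")
    mf = _MAP_FUNCTIONS[mapfun]
    cols = []
    for group in linkage_map.groups:
        R = np.array([ril_expansion(mf(d)) for d in np.diff(group.positions)])
        state = rng.integers(0, 2, size=n)
        block = [state.copy()]
        for r in R:
            flip = rng.random(n) < r
            state = np.where(flip, 1 - state, state)
            block.append(state.copy())
        cols.append(np.stack(block, axis=1))
    codes01 = np.concatenate(cols, axis=1)
    codes = np.where(codes01 == 0, CODE_P1, CODE_P2).astype("U1")
    ril_ids = tuple(f"RIL{i + 1:04d}" for i in range(n))
    return GenotypeMatrix(ril_ids=ril_ids, codes=codes)


def heritability_to_sigma(params_pair, times, h2) -> np.ndarray:
    """Per-trait residual SDs giving heritability ``h2`` at the middle time.

    With the two homozygotes at equal frequency, the genetic variance of
    trait k at the middle measurement time t* is a quarter of the squared
    genotype-mean difference; the residual variance follows from
    sigma_k^2 = sigma_g,k^2 (1 - h2) / h2.
    """
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (3,)).copy()
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValueError("h2 must lie strictly inside (0, 1)")
    times = np.asarray(times, dtype=float)
    t_star = times[len(times) // 2]
    mus = [solve_trajectory(p, np.array([times[0], t_star])).organs()[-1] for p in params_pair]
    diff = mus[0] - mus[1]
    if np.any(diff == 0):
        raise ValueError("genotype means coincide at the middle time; h2 scaling undefined")
    sigma_g2 = 0.25 * diff ** 2
    return np.sqrt(sigma_g2 * (1.0 - h2) / h2)


def simulate_phenotypes(
    genomes: GenotypeMatrix,
    linkage_map: LinkageMap,
    qtl: tuple[str, float],
    params_pair,
    sigma,
    times,
    seed: int | np.random.Generator = 0,
    mapfun: str = "haldane",
    dropout: float = 0.0,
) -> SimDataset:
    """Phenotypes = genotype ODE mean curve + white noise, truth recorded.

    When the QTL coincides with a marker each line's QTL genotype is read
    off its simulated chromosome; otherwise it is drawn from the
    conditional probabilities given the flanking markers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (3,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    qtl_group, qtl_cm = qtl
    pos = locate(linkage_map, qtl_group, qtl_cm)
    if pos.d1 < 1e-12:
        assign = (genomes.codes[:, pos.left_index] == CODE_P2).astype(int)
    elif pos.d2 < 1e-12:
        assign = (genomes.codes[:, pos.right_index] == CODE_P2).astype(int)
    else:
        omega = qtl_genotype_probs(genomes, linkage_map, pos, mapfun=mapfun)
        assign = (rng.random(genomes.n) >= omega[:, 0]).astype(int)

    curves = np.stack([solve_trajectory(p, times).organs() for p in params_pair])
    series = []
    for i, rid in enumerate(genomes.ril_ids):
        mu = curves[assign[i]]
        y = mu + rng.standard_normal(mu.shape) * sigma[None, :]
        t_i, y_i = times, y
        if dropout > 0:
            keep = rng.random(len(times)) >= dropout
            if keep.sum() < 4:  # keep enough points for a cubic basis
                keep[:] = True
            t_i, y_i = times[keep], y[keep]
        series.append(TraitSeries(rid, t_i, y_i))
    truth = {
        "qtl_group": qtl_group,
        "qtl_cm": float(qtl_cm),
        "assignment": assign,
        "params": [p.to_dict() for p in params_pair],
        "sigma": np.asarray(sigma).tolist(),
        "times": times.tolist(),
    }
    return SimDataset(linkage_map=linkage_map, genotypes=genomes,
                      panel=PhenotypePanel(series), truth=truth)


def simulate_dataset(
    config: SimConfig,
    params_pair=(GENOTYPE1_PARAMS, GENOTYPE2_PARAMS),
    null: bool = False,
    null_params: OdeParams | None = None,
) -> SimDataset:
    """Genomes + phenotypes in one call; ``null=True`` gives a no-QTL dataset.

    Under the null every line shares one generating curve
    (``null_params``, default :data:`NULL_PARAMS`) while the residual SDs
    still come from the alternative pair's heritability scaling, so null
    and QTL replicates are matched in noise.
    """
    rng = np.random.default_rng(config.seed)
    genomes = simulate_ril_genomes(config.linkage_map, config.n_rils,
                                   config.generation, rng, config.mapfun)
    sigma = config.sigma
    if sigma is None:
        sigma = heritability_to_sigma(params_pair, config.times, config.h2)
    qtl = config.resolved_qtl()
    pair = params_pair
    if null:
        np_ = null_params or NULL_PARAMS
        pair = (np_, np_)
    ds = simulate_phenotypes(genomes, config.linkage_map, qtl, pair, sigma,
                             config.times, rng, config.mapfun, config.dropout)
    ds.truth["seed"] = config.seed
    ds.truth["null"] = bool(null)
    ds.truth["h2"] = None if config.sigma is not None else config.h2
    return ds
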