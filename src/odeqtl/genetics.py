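"""Linkage-map arithmetic and conditional QTL-genotype probabilities for RILs.

A recombinant inbred line (RIL) derived by repeated selfing is homozygous
at essentially every locus, carrying one of the two parental alleles.
Between two loci at meiotic recombination fraction ``r`` the chance that a
RIL chromosome is recombinant is inflated by the accumulated meioses to
``R = 2r/(1+2r)`` (selfed-RIL expansion). Interval mapping places a
putative QTL between two flanking markers and, for each line, converts the
observed flank genotypes into the conditional probability of each QTL
genotype using these expanded fractions under a no-interference (product)
model across the two sub-intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Genotype codes: parent-1 homozygote, parent-2 homozygote, missing.
CODE_P1 = "A"
CODE_P2 = "B"
CODE_MISSING = "-"
_VALID_CODES = {CODE_P1, CODE_P2, CODE_MISSING}


def haldane_cm_to_r(d: float) -> float:
    """Haldane map function: genetic distance (cM) -> recombination fraction.

    r = (1 - exp(-2d/100)) / 2, assuming no crossover interference.
    """
    if d < 0:
        raise ValueError(f"genetic distance must be non-negative, got {d}")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def kosambi_cm_to_r(d: float) -> float:
    """Kosambi map function: r = tanh(2d/100) / 2 (partial interference)."""
    if d < 0:
        raise ValueError(f"genetic distance must be non-negative, got {d}")
    return 0.5 * np.tanh(2.0 * d / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane_cm_to_r, "kosambi": kosambi_cm_to_r}


def ril_expansion(r: float) -> float:
    """Selfed-RIL recombination expansion R = 2r/(1+2r).

    Repeated selfing gives recombination repeated chances to occur, so the
    fraction of recombinant RIL chromosomes exceeds the per-meiosis
    fraction; at full linkage (r=0) and free recombination (r=1/2) the
    expansion is the identity.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")
    return 2.0 * r / (1.0 + 2.0 * r)


def fixation_probability(generation: int) -> float:
    """Probability a locus is fixed (homozygous) by the F_g selfing generation.

    f = 1 - 0.5**(g-1); at F7 this is 0.984, justifying the treatment of
    the population as fully homozygous.
    """
    if generation < 2:
        raise ValueError("selfing generations start at F2")
    return 1.0 - 0.5 ** (generation - 1)


@dataclass(frozen=True)
class LinkageGroup:
    name: str
    markers: tuple[str, ...]
    positions: np.ndarray  # cM, strictly increasing

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.markers) != len(pos):
            raise ValueError("marker names and positions differ in length")
        if len(pos) and (pos[0] < 0 or np.any(np.diff(pos) <= 0)):
            raise ValueError(
                f"positions in group {self.name!r} must be non-negative and strictly increasing"
            )

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass(frozen=True)
class LinkageMap:
    """Ordered markers with cM positions, grouped into linkage groups."""

    groups: tuple[LinkageGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [m for g in self.groups for m in g.markers]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique genome-wide")

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def marker_names(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    def group(self, name: str) -> LinkageGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no linkage group named {name!r}")

    def marker_index(self, marker: str) -> int:
        """Genome-wide column index of a marker (map order)."""
        i = 0
        for g in self.groups:
            for m in g.markers:
                if m == marker:
                    return i
                i += 1
        raise KeyError(f"unknown marker {marker!r}")

    def group_offset(self, name: str) -> int:
        i = 0
        for g in self.groups:
            if g.name == name:
                return i
            i += len(g.markers)
        raise KeyError(f"no linkage group named {name!r}")


@dataclass(frozen=True)
class GenotypeMatrix:
    """RIL x marker homozygote codes ('A', 'B', '-'), columns in map order."""

    ril_ids: tuple[str, ...]
    codes: np.ndarray  # (n, M) of str

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype="U1")
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2 or codes.shape[0] != len(self.ril_ids):
            raise ValueError("codes must be (n_rils, n_markers)")
        bad = set(np.unique(codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class QtlPosition:
    """A putative QTL location inside (or at) a marker interval."""

    group: str
    cm: float
    left_index: int   # genome-wide column index of the left flank
    right_index: int
    d1: float  # cM from left flank to QTL
    d2: float  # cM from QTL to right flank

    def __post_init__(self):
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("flank distances must be non-negative")


def locate(linkage_map: LinkageMap, group: str, cm: float) -> QtlPosition:
    """Resolve a (group, cM) pair to its flanking-marker interval."""
    g = linkage_map.group(group)
    pos = g.positions
    if len(pos) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 markers; cannot scan")
    if cm < pos[0] or cm > pos[-1]:
        raise ValueError(f"position {cm} cM outside group {group!r} span [{pos[0]}, {pos[-1]}]")
    off = linkage_map.group_offset(group)
    j = int(np.searchsorted(pos, cm, side="right")) - 1
    j = min(max(j, 0), len(pos) - 2)
    return QtlPosition(
        group=group, cm=float(cm),
        left_index=off + j, right_index=off + j + 1,
        d1=float(cm - pos[j]), d2=float(pos[j + 1] - cm),
    )


def _expanded_r(d_cm: float, mapfun: str) -> float:
    try:
        f = _MAP_FUNCTIONS[mapfun]
    except KeyError:
        raise ValueError(f"unknown map function {mapfun!r}; use 'haldane' or 'kosambi'")
    return ril_expansion(f(d_cm))


def qtl_genotype_probs(
    geno: GenotypeMatrix,
    linkage_map: LinkageMap,
    pos: QtlPosition,
    mapfun: str = "haldane",
) -> np.ndarray:
    """Conditional probabilities omega[i, j] of QTL genotype j per RIL i.

    j = 0 is the parent-1 ('A') homozygote, j = 1 the parent-2 ('B')
    homozygote. Given both flank genotypes, the joint probability of the
    QTL genotype is the product of (recombinant | non-recombinant) terms
    for the two sub-intervals with RIL-expanded fractions, normalized over
    the two QTL genotypes. A missing flank drops its factor (conditioning
    on the informative flank only); both missing gives the (1/2, 1/2)
    prior. Rows sum to one by construction.
    """
    if geno.n_markers != linkage_map.n_markers:
        raise ValueError("genotype matrix and linkage map disagree on marker count")
    R1 = _expanded_r(pos.d1, mapfun)
    R2 = _expanded_r(pos.d2, mapfun)
    left = geno.codes[:, pos.left_index]
    right = geno.codes[:, pos.right_index]

    # P(QTL = A | flank) factors: non-recombinant prob if flank is A,
    # recombinant prob if flank is B, 1 if missing.
    def factor(codes: np.ndarray, R: float) -> np.ndarray:
        f = np.ones(len(codes))
        f[codes == CODE_P1] = 1.0 - R
        f[codes == CODE_P2] = R
        return f

    pA = factor(left, R1) * factor(right, R2)
    # complementary factors for QTL = B
    fB_left = np.ones(geno.n)
    fB_left[left == CODE_P1] = R1
    fB_left[left == CODE_P2] = 1.0 - R1
    fB_right = np.ones(geno.n)
    fB_right[right == CODE_P1] = R2
    fB_right[right == CODE_P2] = 1.0 - R2
    pB = fB_left * fB_right

    total = pA + pB
    omega = np.column_stack([pA / total, pB / total])
    return omega
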