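"""The synthetic RIL design generator."""

import numpy as np
import pytest

from odeqtl.genetics import CODE_P1, CODE_P2, haldane_cm_to_r, ril_expansion
from odeqtl.simulate import (
    GENOTYPE1_PARAMS, GENOTYPE2_PARAMS, NULL_PARAMS, SimConfig,
    default_linkage_map, heritability_to_sigma, simulate_dataset,
    simulate_phenotypes, simulate_ril_genomes, small_linkage_map,
)
from odeqtl.trait_ode import solve_trajectory


class TestGenomes:
    def test_default_map_dimensions(self):
        lmap = default_linkage_map()
        assert len(lmap.groups) == 25
        assert lmap.n_markers == 950

    def test_zero_distance_markers_identical(self):
        from odeqtl.genetics import LinkageGroup, LinkageMap

        lmap = LinkageMap((LinkageGroup("1", ("a", "b", "c"),
                                        np.array([0.0, 1e-12, 10.0])),))
        g = simulate_ril_genomes(lmap, 200, seed=1)
        assert np.array_equal(g.codes[:, 0], g.codes[:, 1])

    def test_adjacent_marker_recombination_matches_expansion(self):
        """Observed recombinant fraction across a 10 cM interval matches
        the selfed-RIL expansion R = 2r/(1+2r) within a binomial CI."""
        lmap = small_linkage_map(n_markers=2, spacing_cm=10.0)
        n = 2000
        g = simulate_ril_genomes(lmap, n, seed=42)
        rec = np.mean(g.codes[:, 0] != g.codes[:, 1])
        R = ril_expansion(haldane_cm_to_r(10.0))
        se = np.sqrt(R * (1 - R) / n)
        assert abs(rec - R) < 4 * se

    def test_unlinked_groups_uncorrelated(self):
        from odeqtl.genetics import LinkageGroup, LinkageMap

        lmap = LinkageMap((
            LinkageGroup("1", ("a1", "a2"), np.array([0.0, 10.0])),
            LinkageGroup("2", ("b1", "b2"), np.array([0.0, 10.0])),
        ))
        g = simulate_ril_genomes(lmap, 500, seed=3)
        x = (g.codes == CODE_P2).astype(float)
        r = np.corrcoef(x[:, 0], x[:, 2])[0, 1]
        assert abs(r) < 0.1

    def test_marker_segregation_one_to_one(self):
        """Markers segregate ~1:1; chi-square not rejected for >=95%."""
        from scipy.stats import chi2

        lmap = small_linkage_map(n_markers=20, spacing_cm=5.0)
        n = 500
        g = simulate_ril_genomes(lmap, n, seed=8)
        counts = (g.codes == CODE_P1).sum(axis=0)
        stat = (2 * counts - n) ** 2 / n
        frac_ok = np.mean(stat < chi2.ppf(0.99, df=1))
        assert frac_ok >= 0.95


class TestHeritabilityScaling:
    def test_simple_case(self):
        """h2 = 0.5 with genotype-mean difference 2 gives unit variance."""
        pair = (GENOTYPE1_PARAMS, GENOTYPE2_PARAMS)
        times = np.linspace(20, 120, 6)
        t_star = times[len(times) // 2]
        mus = [solve_trajectory(p, np.array([20.0, t_star])).organs()[-1] for p in pair]
        d = mus[0] - mus[1]
        sigma = heritability_to_sigma(pair, times, 0.5)
        assert np.allclose(sigma ** 2, 0.25 * d ** 2, rtol=1e-8)

    def test_oracle_recomputation_default_pair(self):
        """Spreadsheet-style recomputation of the default-design SDs at
        h2 = 0.05: sigma_k = sqrt(d_k^2/4 * 19)."""
        pair = (GENOTYPE1_PARAMS, GENOTYPE2_PARAMS)
        times = np.linspace(20, 120, 6)
        mus = [solve_trajectory(p, times).organs()[3] for p in pair]  # t* = day 80
        d = mus[0] - mus[1]
        want = np.sqrt(0.25 * d ** 2 * (1 - 0.05) / 0.05)
        got = heritability_to_sigma(pair, times, 0.05)
        assert np.allclose(got, want, rtol=1e-8)

    def test_noise_vanishes_as_h2_approaches_one(self):
        pair = (GENOTYPE1_PARAMS, GENOTYPE2_PARAMS)
        times = np.linspace(20, 120, 6)
        assert np.all(heritability_to_sigma(pair, times, 0.999) <
                      0.1 * heritability_to_sigma(pair, times, 0.5))

    def test_identical_means_rejected(self):
        with pytest.raises(ValueError):
            heritability_to_sigma((NULL_PARAMS, NULL_PARAMS), np.linspace(20, 120, 6), 0.05)


class TestPhenotypes:
    def test_zero_noise_reproduces_mean_curves(self, tiny_map):
        cfg = SimConfig(seed=5, n_rils=12, linkage_map=tiny_map,
                        qtl_group="g01", qtl_cm=10.0, sigma=np.zeros(3))
        ds = simulate_dataset(cfg)
        times = np.asarray(cfg.times)
        curves = [solve_trajectory(p, times).organs()
                  for p in (GENOTYPE1_PARAMS, GENOTYPE2_PARAMS)]
        for i, s in enumerate(ds.panel.series):
            assert np.allclose(s.values, curves[ds.truth["assignment"][i]], atol=1e-9)

    def test_seed_determinism(self, tiny_map):
        cfg = SimConfig(seed=77, n_rils=10, linkage_map=tiny_map, h2=0.3)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.panel.content_hash() == b.panel.content_hash()
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        c = simulate_dataset(cfg.replace(seed=78))
        assert c.panel.content_hash() != a.panel.content_hash()

    def test_marker_qtl_assignment_reads_chromosome(self, tiny_map):
        cfg = SimConfig(seed=9, n_rils=50, linkage_map=tiny_map,
                        qtl_group="g01", qtl_cm=10.0, h2=0.3)
        ds = simulate_dataset(cfg)
        marker_col = ds.genotypes.codes[:, 1]  # middle marker at 10 cM
        assert np.array_equal(ds.truth["assignment"],
                              (marker_col == CODE_P2).astype(int))

    def test_empirical_heritability_calibration(self):
        """At large n the realized mid-season heritability per trait is
        close to the nominal 0.05 target."""
        lmap = small_linkage_map(n_markers=3, spacing_cm=10.0)
        cfg = SimConfig(seed=123, n_rils=5000, linkage_map=lmap,
                        qtl_group="g01", qtl_cm=10.0, h2=0.05)
        ds = simulate_dataset(cfg)
        t_idx = 3  # middle measurement (day 80)
        Y = np.stack([s.values for s in ds.panel.series])[:, t_idx, :]
        assign = ds.truth["assignment"]
        h2_hats = []
        for k in range(3):
            means = np.array([Y[assign == j, k].mean() for j in (0, 1)])
            freqs = np.array([(assign == j).mean() for j in (0, 1)])
            grand = freqs @ means
            var_g = freqs @ (means - grand) ** 2
            h2_hats.append(var_g / Y[:, k].var())
        # per-trait estimates carry Monte-Carlo error ~0.006 even at this
        # n; the across-trait mean is the calibrated quantity
        assert abs(np.mean(h2_hats) - 0.05) < 0.01

    def test_dropout_produces_ragged_grids(self, tiny_map):
        cfg = SimConfig(seed=4, n_rils=30, linkage_map=tiny_map, h2=0.3, dropout=0.25)
        ds = simulate_dataset(cfg)
        lengths = {s.m for s in ds.panel.series}
        assert min(lengths) >= 4 and len(lengths) > 1

    def test_null_dataset_single_curve(self, tiny_map):
        cfg = SimConfig(seed=6, n_rils=8, linkage_map=tiny_map,
                        sigma=np.zeros(3))
        ds = simulate_dataset(cfg, null=True)
        base = ds.panel.series[0].values
        for s in ds.panel.series[1:]:
            assert np.allclose(s.values, base, atol=1e-9)
        assert ds.truth["null"] is True

    def test_sigma_validation(self, tiny_map):
        genomes = simulate_ril_genomes(tiny_map, 5, seed=1)
        with pytest.raises(ValueError):
            simulate_phenotypes(genomes, tiny_map, ("g01", 10.0),
                                (GENOTYPE1_PARAMS, GENOTYPE2_PARAMS),
                                sigma=-1.0, times=np.linspace(20, 120, 6))
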