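"""Mixture likelihood and the parameter-cascading estimator."""

import numpy as np
import pytest

from odeqtl.estimation import (
    FitConfig, NoiseModel, bootstrap_se, fit_m0, fit_m1,
    gradient_matching_init, lr_statistic, mixture_loglik,
)
from odeqtl.io import PhenotypePanel, TraitSeries
from odeqtl.simulate import SimConfig, simulate_dataset, small_linkage_map
from odeqtl.trait_ode import OdeParams, solve_trajectory

# well-conditioned generating pair for self-consistency checks: moderate
# elimination rates (relaxation times comparable to the sampling
# interval) keep every parameter identifiable from the trajectories
RECOV_P1 = OdeParams(2.5, 0.10, 0.30, 1.00, 0.04, 1.10, 0.51, 0.50)
RECOV_P2 = OdeParams(1.9, 0.14, 0.20, 1.04, 0.07, 1.10, 0.56, 0.35)
RECOV_TIMES = np.linspace(20.0, 120.0, 11)

PRECISE = FitConfig(n_starts=1, simplex_maxfev=0, outer_rounds=2,
                    max_outer_iter=250, knot_refine=3,
                    basin_gammas=(0.06, 0.2, 0.7, 2.2), basin_maxiter=30,
                    basin_rounds=2)


def _brute_force_mixture(panel, omega, mu, sigma2):
    """Term-by-term evaluation of the mixture likelihood (tiny n only)."""
    total = 0.0
    for i, s in enumerate(panel.series):
        mix = 0.0
        for j in range(omega.shape[1]):
            dens = 1.0
            for k in range(3):
                for t in range(s.m):
                    r = s.values[t, k] - mu[j, t, k]
                    dens *= np.exp(-0.5 * r ** 2 / sigma2[k]) / np.sqrt(2 * np.pi * sigma2[k])
            mix += omega[i, j] * dens
        total += np.log(mix)
    return total


@pytest.fixture(scope="module")
def tiny_mixture():
    rng = np.random.default_rng(17)
    times = np.array([10.0, 20.0])
    panel = PhenotypePanel([
        TraitSeries(f"r{i}", times, rng.normal(5.0, 1.0, (2, 3))) for i in range(3)
    ])
    omega = np.array([[0.9, 0.1], [0.4, 0.6], [0.5, 0.5]])
    mu = rng.normal(5.0, 1.0, (2, 2, 3))
    sigma2 = np.array([0.8, 1.2, 0.6])
    return panel, omega, mu, sigma2


class TestMixtureLoglik:
    def test_matches_brute_force_oracle(self, tiny_mixture):
        panel, omega, mu, sigma2 = tiny_mixture
        got = mixture_loglik(panel, omega, mu, NoiseModel(sigma2=sigma2))
        want = _brute_force_mixture(panel, omega, mu, sigma2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_degenerate_mixture_equals_single_component(self, tiny_mixture):
        panel, _, mu, sigma2 = tiny_mixture
        omega = np.tile([1.0, 0.0], (3, 1))
        got = mixture_loglik(panel, omega, mu, NoiseModel(sigma2=sigma2))
        want = _brute_force_mixture(panel, np.ones((3, 1)), mu[:1], sigma2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_collapses_when_components_equal(self, tiny_mixture):
        panel, omega, mu, sigma2 = tiny_mixture
        mu_eq = np.stack([mu[0], mu[0]])
        noise = NoiseModel(sigma2=sigma2)
        a = mixture_loglik(panel, omega, mu_eq, noise)
        b = mixture_loglik(panel, omega[:, ::-1], mu_eq, noise)
        c = mixture_loglik(panel, np.full((3, 2), 0.5), mu_eq, noise)
        assert a == pytest.approx(b, abs=1e-10)
        assert a == pytest.approx(c, abs=1e-10)

    def test_label_swap_symmetry(self, tiny_mixture):
        panel, omega, mu, sigma2 = tiny_mixture
        noise = NoiseModel(sigma2=sigma2)
        a = mixture_loglik(panel, omega, mu, noise)
        b = mixture_loglik(panel, omega[:, ::-1], mu[::-1], noise)
        assert a == pytest.approx(b, abs=1e-10)

    def test_ar1_reduces_to_diagonal_at_zero_correlation(self, tiny_mixture):
        panel, omega, mu, sigma2 = tiny_mixture
        a = mixture_loglik(panel, omega, mu, NoiseModel(sigma2=sigma2))
        b = mixture_loglik(panel, omega, mu, NoiseModel(sigma2=sigma2, rho=0.0))
        assert a == pytest.approx(b, abs=1e-8)

    def test_rejects_invalid_noise(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma2=np.array([1.0, -1.0, 1.0]))
        with pytest.raises(ValueError):
            NoiseModel(sigma2=np.ones(3), rho=1.5)


@pytest.fixture(scope="module")
def recovery_dataset():
    lmap = small_linkage_map(n_markers=3, spacing_cm=10.0)
    cfg = SimConfig(seed=7, n_rils=40, linkage_map=lmap, qtl_group="g01",
                    qtl_cm=10.0, sigma=np.array([1e-6, 1e-6, 1e-6]),
                    times=RECOV_TIMES)
    ds = simulate_dataset(cfg, params_pair=(RECOV_P1, RECOV_P2))
    return ds, ds.omega_at_truth()


@pytest.fixture(scope="module")
def recovery_fit(recovery_dataset):
    ds, omega = recovery_dataset
    return fit_m1(ds.panel, omega, PRECISE)


def _direct_ml_oracle(ds, params_pair):
    """Independent route: solve the ODE numerically per genotype and fit
    each genotype group's mean curve by nonlinear least squares (no
    splines anywhere). Returns (J, 8) structural estimates."""
    from scipy.integrate import solve_ivp
    from scipy.optimize import least_squares

    times = np.asarray(ds.truth["times"])
    Y = np.stack([s.values for s in ds.panel.series])
    assign = np.asarray(ds.truth["assignment"])

    def curves(p, ini):
        def f(t, y):
            W = max(y.sum(), 1e-9)
            return [p[0] * W ** p[1] - p[2] * y[0],
                    p[3] * W ** p[4],
                    p[5] * W ** p[6] - p[7] * y[2]]

        sol = solve_ivp(f, (times[0], times[-1]), ini, t_eval=times,
                        rtol=1e-9, atol=1e-11, method="LSODA")
        return sol.y.T

    out = []
    for j, gen in enumerate(params_pair):
        ybar = Y[assign == j].mean(axis=0)

        def resid(x):
            p = x[:8].copy()
            p[[0, 2, 3, 5, 7]] = np.exp(p[[0, 2, 3, 5, 7]])
            try:
                c = curves(p, np.exp(x[8:]))
            except Exception:
                return np.full(times.size * 3, 1e3)
            if c.shape != ybar.shape:
                return np.full(times.size * 3, 1e3)
            return (c - ybar).ravel()

        x0 = np.concatenate([gen.structural, [1.5, 0.5, 0.5]])
        x0[[0, 2, 3, 5, 7]] = np.log(x0[[0, 2, 3, 5, 7]])
        x0[8:] = np.log(x0[8:])
        x0 += np.random.default_rng(31 + j).normal(0, 0.15, 11)  # jittered start
        r = least_squares(resid, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        p = r.x[:8].copy()
        p[[0, 2, 3, 5, 7]] = np.exp(p[[0, 2, 3, 5, 7]])
        out.append(p)
    return np.stack(out)


class TestCascadingFit:
    def test_noiseless_recovery(self, recovery_fit):
        """Noise-free data from two distinct growth systems: the fit
        recovers every structural parameter to a few percent."""
        for est, tru in zip(recovery_fit.params, (RECOV_P1, RECOV_P2)):
            rel = np.abs(est.structural - tru.structural) / np.abs(tru.structural)
            assert rel.max() < 0.05

    def test_agrees_with_direct_ml_oracle(self, recovery_dataset, recovery_fit):
        """Parameter cascading is equivalent to profiling: on a noiseless
        instance it matches a spline-free ODE-solve ML fit within 2%."""
        ds, _ = recovery_dataset
        oracle = _direct_ml_oracle(ds, (RECOV_P1, RECOV_P2))
        est = recovery_fit.structural()
        # 2% relative, with an absolute floor so near-zero exponents are
        # compared on a meaningful scale
        rel = np.abs(est - oracle) / np.maximum(np.abs(oracle), 0.25)
        assert rel.max() < 0.02

    def test_m0_nested_in_m1(self, marker_qtl_dataset, fast_fit_config):
        ds = marker_qtl_dataset
        omega = ds.omega_at_truth()
        m1 = fit_m1(ds.panel, omega, fast_fit_config)
        m0 = fit_m0(ds.panel, fast_fit_config,
                    extra_starts=[(p,) for p in m1.params])
        assert m1.loglik >= m0.loglik - 1e-4
        assert lr_statistic(m1, m0) >= 0.0

    def test_m0_recovers_single_genotype_data(self, tiny_map):
        cfg = SimConfig(seed=13, n_rils=30, linkage_map=tiny_map,
                        sigma=np.array([1e-6, 1e-6, 1e-6]), times=RECOV_TIMES)
        ds = simulate_dataset(cfg, params_pair=(RECOV_P1, RECOV_P1))
        m0 = fit_m0(ds.panel, PRECISE)
        rel = np.abs(m0.params[0].structural - RECOV_P1.structural) / RECOV_P1.structural
        assert rel.max() < 0.05

    def test_m0_pooled_estimates_between_genotype_values(self, tiny_map):
        """On balanced two-genotype data the one-curve fit lands between
        the genotype-specific generating values for the well-identified
        stem parameters."""
        cfg = SimConfig(seed=19, n_rils=60, linkage_map=tiny_map,
                        qtl_group="g01", qtl_cm=10.0,
                        sigma=np.array([0.05, 0.05, 0.05]), times=RECOV_TIMES)
        ds = simulate_dataset(cfg, params_pair=(RECOV_P1, RECOV_P2))
        m0 = fit_m0(ds.panel, PRECISE)
        for idx in (3, 4):  # alpha_S, beta_S
            lo = min(RECOV_P1.structural[idx], RECOV_P2.structural[idx])
            hi = max(RECOV_P1.structural[idx], RECOV_P2.structural[idx])
            v = m0.params[0].structural[idx]
            assert lo - 0.05 * abs(lo) <= v <= hi + 0.05 * abs(hi)

    def test_lr_requires_same_data(self, marker_qtl_dataset, noiseless_dataset,
                                   fast_fit_config):
        m1 = fit_m1(marker_qtl_dataset.panel, marker_qtl_dataset.omega_at_truth(),
                    fast_fit_config)
        m0 = fit_m0(noiseless_dataset.panel, fast_fit_config)
        with pytest.raises(ValueError, match="hash"):
            lr_statistic(m1, m0)

    def test_initializer_targets_levels_and_exponents(self, recovery_dataset):
        """The gradient-matching start lands near the identifiable
        level/exponent combinations for both genotypes."""
        ds, omega = recovery_dataset
        init = gradient_matching_init(ds.panel, omega)
        for est, tru in zip(init, (RECOV_P1, RECOV_P2)):
            assert abs(est.beta_R - tru.beta_R) < 0.15
            assert abs(est.alpha_S - tru.alpha_S) / tru.alpha_S < 0.25


class TestBootstrap:
    def test_se_scale_tracks_noise(self, tiny_map):
        """Near-zero residual noise gives near-zero bootstrap SEs."""
        cfg = SimConfig(seed=29, n_rils=24, linkage_map=tiny_map,
                        qtl_group="g01", qtl_cm=10.0,
                        sigma=np.array([1e-4, 1e-4, 1e-4]), times=RECOV_TIMES)
        ds = simulate_dataset(cfg, params_pair=(RECOV_P1, RECOV_P2))
        omega = ds.omega_at_truth()
        fc = FitConfig(n_starts=1, simplex_maxfev=0, outer_rounds=1,
                       max_outer_iter=120, knot_refine=3, basin_gammas=())
        fit = fit_m1(ds.panel, omega, fc)
        se, est = bootstrap_se(fit, ds.panel, omega, B=3, seed=5, config=fc)
        assert se.shape == (2, 8)
        assert est.shape[0] == 3
        # stem parameters are precisely identified: tiny SEs
        assert np.all(se[:, 3] < 0.05)
        assert np.all(se[:, 4] < 0.05)

    def test_requires_minimum_replicates(self, marker_qtl_dataset, fast_fit_config):
        ds = marker_qtl_dataset
        fit = fit_m1(ds.panel, ds.omega_at_truth(), fast_fit_config)
        with pytest.raises(ValueError):
            bootstrap_se(fit, ds.panel, ds.omega_at_truth(), B=1)
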