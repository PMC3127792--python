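"""B-spline basis machinery and the ODE-penalized inner fit."""

import numpy as np
import pytest

from odeqtl.io import PhenotypePanel, TraitSeries
from odeqtl.smoothing import (
    BasisSystem, build_basis, eval_basis, inner_fit, refined_knots,
)
from odeqtl.trait_ode import OdeParams, solve_trajectory
from odeqtl.simulate import GENOTYPE1_PARAMS


@pytest.fixture(scope="module")
def six_time_basis():
    return build_basis(np.linspace(20, 120, 6))


class TestBasis:
    def test_saturated_knot_count(self):
        basis = build_basis(np.array([0.0, 1.0, 2.0, 3.0]))
        assert basis.n_basis == 2 + 4  # interior knots + order

    def test_partition_of_unity(self, six_time_basis):
        t = np.linspace(20, 120, 57)
        Phi = eval_basis(six_time_basis, t)
        assert np.allclose(Phi.sum(axis=1), 1.0, atol=1e-10)

    def test_compact_support(self, six_time_basis):
        """Each basis function is positive on at most `order` knot spans."""
        spans = np.unique(six_time_basis.knots)
        Phi = eval_basis(six_time_basis, 0.5 * (spans[:-1] + spans[1:]))
        n_active_spans = (np.abs(Phi) > 1e-12).sum(axis=0)
        assert np.all(n_active_spans <= six_time_basis.order)

    def test_derivative_of_constant_is_zero(self, six_time_basis):
        t = np.linspace(20, 120, 33)
        D = eval_basis(six_time_basis, t, deriv=1)
        c = np.ones(six_time_basis.n_basis)
        assert np.allclose(D @ c, 0.0, atol=1e-10)

    def test_derivative_matches_finite_differences(self, six_time_basis):
        t = np.linspace(25, 115, 19)
        h = 1e-5
        D = eval_basis(six_time_basis, t, deriv=1)
        fd = (eval_basis(six_time_basis, t + h) - eval_basis(six_time_basis, t - h)) / (2 * h)
        assert np.allclose(D, fd, atol=1e-6)

    def test_no_extrapolation(self, six_time_basis):
        with pytest.raises(ValueError):
            eval_basis(six_time_basis, [125.0])
        with pytest.raises(ValueError):
            build_basis(np.array([0.0, 1.0, 2.0]))  # fewer than order times

    def test_refined_knots_subdivide_spans(self):
        times = np.array([0.0, 10.0, 30.0])
        interior = refined_knots(times, 2)
        assert np.allclose(interior, [5.0, 10.0, 20.0])

    def test_roundtrip_serialization(self, six_time_basis):
        again = BasisSystem.from_dict(six_time_basis.to_dict())
        assert np.allclose(again.knots, six_time_basis.knots)
        assert again.order == six_time_basis.order


def _noiseless_panel(n=4, times=None):
    times = np.linspace(20, 120, 6) if times is None else times
    Y = solve_trajectory(GENOTYPE1_PARAMS, times).organs()
    return PhenotypePanel([TraitSeries(f"r{i}", times, Y) for i in range(n)]), Y


class TestInnerFit:
    def test_lambda_zero_matches_normal_equations_oracle(self):
        """With the penalty off the inner fit is weighted least squares;
        compare against a direct pseudo-inverse solution."""
        rng = np.random.default_rng(5)
        times = np.linspace(0, 10, 8)
        panel = PhenotypePanel([
            TraitSeries(f"r{i}", times, rng.normal(5.0, 1.0, (8, 3))) for i in range(6)
        ])
        w = rng.uniform(0.2, 1.0, (6, 2))
        w /= w.sum(axis=1, keepdims=True)
        basis = build_basis(times)
        coef = inner_fit(panel, w, [None, None], basis, lam=0.0)
        Phi = eval_basis(basis, times)
        Y = np.stack([s.values for s in panel.series])
        for j in range(2):
            H = w[:, j].sum() * Phi.T @ Phi
            for k in range(3):
                b = Phi.T @ np.einsum("g,gm->m", w[:, j], Y[:, :, k])
                c_oracle = np.linalg.pinv(H) @ b
                assert np.allclose(coef.c[j, :, k], c_oracle, atol=1e-8)

    def test_interpolation_recovers_spline_data(self):
        """Data lying exactly on a spline curve are reproduced at lam=0."""
        times = np.linspace(0, 10, 9)
        basis = build_basis(times)
        rng = np.random.default_rng(2)
        c_true = rng.normal(3.0, 0.5, (basis.n_basis, 3))
        Y = eval_basis(basis, times) @ c_true
        panel = PhenotypePanel([TraitSeries("a", times, Y)])
        coef = inner_fit(panel, np.ones((1, 1)), [None], basis, lam=0.0)
        fitted = eval_basis(basis, times) @ coef.c[0]
        assert np.allclose(fitted, Y, atol=1e-8)

    def test_large_lambda_enforces_ode_fidelity(self):
        """Noise-free trajectories + a strong penalty give curves whose
        derivative tracks the growth law along the whole season."""
        panel, _ = _noiseless_panel()
        times = np.linspace(20, 120, 6)
        basis = build_basis(times, knot_spec=refined_knots(times, 6))
        coef = inner_fit(panel, np.ones((len(panel), 1)), [GENOTYPE1_PARAMS], basis, lam=1e8)
        grid = np.linspace(21, 119, 101)
        mu = coef.curves(grid)[0]
        dmu = coef.curves(grid, deriv=1)[0]
        p = GENOTYPE1_PARAMS
        W = mu.sum(axis=1)
        f = np.column_stack([
            p.alpha_L * W ** p.beta_L - p.gamma_L * mu[:, 0],
            p.alpha_S * W ** p.beta_S,
            p.alpha_R * W ** p.beta_R - p.gamma_R * mu[:, 2],
        ])
        assert np.abs(dmu - f).max() < 1e-2

    def test_descent_property(self):
        """The fitted coefficients do not score worse than perturbed ones."""
        panel, _ = _noiseless_panel()
        times = np.linspace(20, 120, 6)
        basis = build_basis(times, knot_spec=refined_knots(times, 3))
        w = np.ones((len(panel), 1))
        coef = inner_fit(panel, w, [GENOTYPE1_PARAMS], basis, lam=1e2)

        def criterion(C):
            # gtol large -> the solver returns the criterion at C itself
            c2 = inner_fit(panel, w, [GENOTYPE1_PARAMS], basis, lam=1e2,
                           c0=C, max_iter=1, gtol=1e30)
            return c2.criterion

        rng = np.random.default_rng(9)
        for _ in range(5):
            C0 = coef.c + rng.normal(0, 0.05, coef.c.shape)
            assert criterion(coef.c) <= criterion(C0) + 1e-9

    def test_lambda_continuity(self):
        """Coefficients vary continuously along a lambda grid (no jumps)."""
        panel, _ = _noiseless_panel()
        times = np.linspace(20, 120, 6)
        basis = build_basis(times, knot_spec=refined_knots(times, 3))
        w = np.ones((len(panel), 1))
        lams = np.geomspace(1e1, 1e3, 7)
        prev = None
        for lam in lams:
            coef = inner_fit(panel, w, [GENOTYPE1_PARAMS], basis, lam=lam)
            if prev is not None:
                rel = np.abs(coef.c - prev) / (1 + np.abs(prev))
                assert rel.max() < 0.2
            prev = coef.c

    def test_rejects_negative_lambda(self):
        panel, _ = _noiseless_panel()
        basis = build_basis(np.linspace(20, 120, 6))
        with pytest.raises(ValueError):
            inner_fit(panel, np.ones((len(panel), 1)), [GENOTYPE1_PARAMS], basis, lam=-1.0)
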