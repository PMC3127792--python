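"""Cubic B-spline machinery and the ODE-penalized inner coefficient fit.

The mean trajectory of trait ``k`` under genotype ``j`` is represented as
a linear combination of cubic B-spline basis functions,
``mu_kj(t) = phi(t)' c_kj``. Knots are saturated (one at every observed
measurement time) and over-fitting is controlled not by knot selection but
by a roughness penalty that measures infidelity to the growth ODE system:

    U(c | Theta) = sum_kji  w_ji * ||y_ki - Phi c_kj||^2 / sigma_k^2
                 + lambda * sum_kj Int [ dmu_kj/dt - f_k(mu_j(t); Theta_j) ]^2 dt

where ``f`` is the allometric partitioning right-hand side and the
integral is evaluated by Gauss-Legendre quadrature on each knot span.
Minimizing U for fixed structural parameters Theta is the *inner* level
of the parameter-cascading estimator; the data term is quadratic in ``c``
and the penalty mildly nonlinear, so a damped Gauss-Newton iteration
converges in a handful of steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .trait_ode import OdeParams

_W_FLOOR = 1e-2  # grams; guard for W**beta when a spline iterate dips non-positive


class InnerFitError(RuntimeError):
    """Inner Gauss-Newton failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_coefficients: np.ndarray):
        super().__init__(message)
        self.last_coefficients = last_coefficients


@dataclass(frozen=True)
class BasisSystem:
    """A cubic B-spline basis on [t0, tmax] with saturated interior knots."""

    knots: np.ndarray          # full knot vector, boundary multiplicity = order
    order: int = 4             # polynomial order (degree + 1); 4 = cubic

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if np.any(np.diff(knots) < 0):
            raise ValueError("knot vector must be non-decreasing")

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def n_basis(self) -> int:
        """R = number of basis functions = len(knots) - order."""
        return len(self.knots) - self.order

    @property
    def t_range(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.order])

    def _spline(self) -> BSpline:
        return BSpline(self.knots, np.eye(self.n_basis), self.degree)

    def quadrature(self, points_per_span: int = 5) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Legendre nodes and weights over every interior knot span."""
        spans = np.unique(self.knots)
        x0, w0 = np.polynomial.legendre.leggauss(points_per_span)
        nodes, weights = [], []
        for a, b in zip(spans[:-1], spans[1:]):
            h = 0.5 * (b - a)
            nodes.append(h * x0 + 0.5 * (a + b))
            weights.append(h * w0)
        return np.concatenate(nodes), np.concatenate(weights)

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "order": self.order}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSystem":
        return cls(knots=np.asarray(d["knots"], dtype=float), order=int(d["order"]))


def refined_knots(times, factor: int) -> np.ndarray:
    """Interior knots: observed times plus ``factor - 1`` subdivisions per span.

    The saturated observed-time grid is the minimal choice; subdividing
    each measurement interval gives the basis enough resolution to track
    an ODE solution between widely spaced observations, which matters for
    the fidelity penalty at large weights.
    """
    times = np.unique(np.asarray(times, dtype=float))
    if factor < 1:
        raise ValueError("refinement factor must be >= 1")
    knots = np.unique(np.concatenate([
        np.linspace(a, b, factor + 1) for a, b in zip(times[:-1], times[1:])
    ]))
    return knots[1:-1]


def build_basis(times, knot_spec=None, order: int = 4) -> BasisSystem:
    """Build a saturated-knot basis from the pooled observed times.

    Interior knots sit at every distinct observed time strictly inside the
    range; boundary knots are repeated to full multiplicity. With ``m``
    distinct times this gives ``R = (m - 2) + order`` basis functions.
    ``knot_spec`` may override with an explicit interior-knot array (for
    example :func:`refined_knots`).
    """
    times = np.unique(np.asarray(times, dtype=float))
    if len(times) < order:
        raise ValueError(f"need at least {order} distinct times for an order-{order} basis")
    t0, tmax = times[0], times[-1]
    interior = np.asarray(knot_spec, dtype=float) if knot_spec is not None else times[1:-1]
    if np.any((interior <= t0) | (interior >= tmax)):
        raise ValueError("interior knots must lie strictly inside the time range")
    knots = np.concatenate([np.full(order, t0), np.sort(interior), np.full(order, tmax)])
    return BasisSystem(knots=knots, order=order)


def eval_basis(basis: BasisSystem, t, deriv: int = 0) -> np.ndarray:
    """Design matrix of basis values (deriv=0) or first derivatives (deriv=1)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = basis.t_range
    if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
        raise ValueError(f"evaluation times outside basis range [{lo}, {hi}]")
    sp = basis._spline()
    if deriv == 0:
        out = sp(t)
    elif deriv == 1:
        out = sp.derivative()(t)
    else:
        raise ValueError("deriv must be 0 or 1")
    return np.asarray(out)


@dataclass
class Coefficients:
    """Fitted basis coefficients, one (R, 3) block per genotype."""

    c: np.ndarray              # (J, R, 3): genotype, basis index, trait
    basis: BasisSystem
    criterion: float = np.nan  # achieved U(c|Theta)
    n_iter: int = 0
    converged: bool = True

    def curves(self, t, deriv: int = 0) -> np.ndarray:
        """Genotype mean curves: (J, len(t), 3)."""
        Phi = eval_basis(self.basis, t, deriv=deriv)
        return np.einsum("mr,jrk->jmk", Phi, self.c)

    def to_dict(self) -> dict:
        return {"c": self.c.tolist(), "basis": self.basis.to_dict(), "criterion": float(self.criterion)}


def _rhs_and_jac(mu: np.ndarray, theta: OdeParams):
    """f(mu) (Q,3) and df/dmu (Q,3,3) at spline states, W floored at 0+.

    Below the floor the power terms are held constant (zero derivative),
    which keeps the Gauss-Newton iteration finite if an iterate's curve
    dips non-positive between knots.
    """
    W_raw = mu.sum(axis=1)
    W = np.maximum(W_raw, _W_FLOOR)
    active = (W_raw > _W_FLOOR).astype(float)
    p = theta
    powL, powS, powR = W ** p.beta_L, W ** p.beta_S, W ** p.beta_R
    f = np.column_stack([
        p.alpha_L * powL - p.gamma_L * mu[:, 0],
        p.alpha_S * powS,
        p.alpha_R * powR - p.gamma_R * mu[:, 2],
    ])
    dL = p.alpha_L * p.beta_L * powL / W * active
    dS = p.alpha_S * p.beta_S * powS / W * active
    dR = p.alpha_R * p.beta_R * powR / W * active
    J = np.empty((len(W), 3, 3))
    J[:, 0, :] = dL[:, None]
    J[:, 1, :] = dS[:, None]
    J[:, 2, :] = dR[:, None]
    J[:, 0, 0] -= p.gamma_L
    J[:, 2, 2] -= p.gamma_R
    return f, J


def _rhs_theta_derivs(mu: np.ndarray, theta: OdeParams):
    """First derivatives of f wrt the 8 structural parameters.

    Returns dict p -> (organ index o, dr (Q,), dJf (Q, 3)) where
    dr = -d f_o / d theta_p evaluated at the spline states (the residual
    derivative) and dJf[:, l] = d(df_o/dmu_l)/d theta_p.
    """
    W = np.maximum(mu.sum(axis=1), _W_FLOOR)
    logW = np.log(W)
    p = theta
    out = {}
    for pidx, o, alpha, beta, gamma in (
        (0, 0, p.alpha_L, p.beta_L, p.gamma_L),      # alpha_L block
        (5, 2, p.alpha_R, p.beta_R, p.gamma_R),
    ):
        powb = W ** beta
        powb1 = W ** (beta - 1.0)
        # alpha
        out[pidx] = (o, -powb, np.repeat((beta * powb1)[:, None], 3, axis=1))
        # beta
        dj = alpha * powb1 * (1.0 + beta * logW)
        out[pidx + 1] = (o, -alpha * powb * logW, np.repeat(dj[:, None], 3, axis=1))
        # gamma
        djg = np.zeros((len(W), 3))
        djg[:, o] = -1.0
        out[pidx + 2] = (o, mu[:, o].copy(), djg)
    # stem: alpha_S (3), beta_S (4); no elimination term
    powb = W ** p.beta_S
    powb1 = W ** (p.beta_S - 1.0)
    out[3] = (1, -powb, np.repeat((p.beta_S * powb1)[:, None], 3, axis=1))
    dj = p.alpha_S * powb1 * (1.0 + p.beta_S * logW)
    out[4] = (1, -p.alpha_S * powb * logW, np.repeat(dj[:, None], 3, axis=1))
    return out


def _rhs_hessian_scalar(mu: np.ndarray, theta: OdeParams) -> np.ndarray:
    """d^2 f_k / dmu_l dmu_n, constant over (l, n): (Q, 3) of scalars."""
    W = np.maximum(mu.sum(axis=1), _W_FLOOR)
    active = (mu.sum(axis=1) > _W_FLOOR).astype(float)
    p = theta
    return np.column_stack([
        p.alpha_L * p.beta_L * (p.beta_L - 1.0) * W ** (p.beta_L - 2.0),
        p.alpha_S * p.beta_S * (p.beta_S - 1.0) * W ** (p.beta_S - 2.0),
        p.alpha_R * p.beta_R * (p.beta_R - 1.0) * W ** (p.beta_R - 2.0),
    ]) * active[:, None]


class _InnerProblem:
    """Precompressed sufficient statistics for one inner fit.

    The data term depends on the sample only through, per time-grid group
    g and genotype j, the weight mass n_jg = sum_i w_ij and the weighted
    sum of observations; the fit cost is therefore independent of the
    number of lines.
    """

    def __init__(self, panel, weights, basis: BasisSystem, sigma2, quad_points: int = 5):
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        self.J = weights.shape[1]
        self.basis = basis
        self.R = basis.n_basis
        self.sigma2 = np.asarray(sigma2, dtype=float)
        groups = panel.grid_groups()  # list of (times, member_indices)
        self.blocks = []
        self.block_times = []
        for times, idx in groups:
            Phi = eval_basis(basis, times)                      # (m, R)
            w = weights[idx]                                    # (ng, J)
            n_j = w.sum(axis=0)                                 # (J,)
            Y = panel.values_stack(idx)                         # (ng, m, 3)
            A_j = np.einsum("gj,gmk->jmk", w, Y)                # (J, m, 3)
            S2_j = np.einsum("gj,gmk->jk", w, Y ** 2)           # (J, 3)
            self.blocks.append((Phi, n_j, A_j, S2_j))
            self.block_times.append(times)
        self._dq_cache: dict = {}
        self.qx, self.qw = basis.quadrature(quad_points)
        self.Phi_q = eval_basis(basis, self.qx)
        self.D_q = eval_basis(basis, self.qx, deriv=1)
        self.DtWD = (self.D_q * self.qw[:, None]).T @ self.D_q
        lo, hi = basis.t_range
        self._dense_t = np.linspace(lo, hi, 8 * self.R)
        self._dense_pinv = np.linalg.pinv(eval_basis(basis, self._dense_t))

    def smooth_start(self, j: int) -> np.ndarray:
        """Coefficients tracking a cubic interpolation of genotype j's mean data.

        Min-norm least-squares starts oscillate wildly when the basis is
        much richer than the data grid; projecting a shape-faithful
        interpolant onto the basis gives Gauss-Newton a benign start.
        """
        from scipy.interpolate import CubicSpline

        g = int(np.argmax([b[1][j] for b in self.blocks]))
        Phi, n_j, A_j, _ = self.blocks[g]
        times = self.block_times[g]
        ybar = A_j[j] / max(n_j[j], 1e-12)                      # (m, 3)
        dense = np.column_stack([
            CubicSpline(times, ybar[:, k])(self._dense_t) for k in range(3)
        ])
        # noisy means can interpolate below zero; a positive start keeps
        # the power terms of the penalty well-behaved
        dense = np.maximum(dense, 0.05)
        C = self._dense_pinv @ dense                            # (R, 3)
        return C.T.reshape(-1)

    def data_quadratics(self, j: int):
        """H (3R x 3R block-diag), b (3R,), const for genotype j's data term."""
        key = (j, self.sigma2.tobytes())
        cached = self._dq_cache.get(key)
        if cached is not None:
            return cached
        R = self.R
        H = np.zeros((3 * R, 3 * R))
        b = np.zeros(3 * R)
        const = 0.0
        for Phi, n_j, A_j, S2_j in self.blocks:
            G = Phi.T @ Phi
            for k in range(3):
                sl = slice(k * R, (k + 1) * R)
                H[sl, sl] += n_j[j] * G / self.sigma2[k]
                b[sl] += Phi.T @ A_j[j, :, k] / self.sigma2[k]
                const += S2_j[j, k] / self.sigma2[k]
        self._dq_cache[key] = (H, b, const)
        return H, b, const


def _genotype_objective(prob: _InnerProblem, Hbc, theta: OdeParams, lam: float, x: np.ndarray):
    """U contribution, gradient and GN normal matrix for one genotype block."""
    R = prob.R
    C = x.reshape(3, R).T                      # (R, 3)
    H, b, const = Hbc
    val = const - 2.0 * b @ x + x @ (H @ x)
    grad = 2.0 * (H @ x - b)
    GN = 2.0 * H
    if lam > 0:
        qw, Phi, D = prob.qw, prob.Phi_q, prob.D_q
        mu = Phi @ C                           # (Q, 3)
        dmu = D @ C
        f, Jf = _rhs_and_jac(mu, theta)
        r = dmu - f                            # (Q, 3)
        val += lam * np.einsum("q,qk->", qw, r ** 2)
        # residual Jacobian: d r_qk / d C[m,l] = delta_kl D[q,m] - Jf[q,k,l] Phi[q,m]
        wr = qw[:, None] * r
        rJ = np.einsum("qk,qkl->ql", r, Jf)    # sum_k r_qk Jf[q,k,l]
        for l in range(3):
            sl = slice(l * R, (l + 1) * R)
            grad[sl] += 2.0 * lam * (D.T @ wr[:, l] - Phi.T @ (qw * rJ[:, l]))
        G2 = np.einsum("qkl,qkn->qln", Jf, Jf)  # sum_k Jf[q,k,l] Jf[q,k,n]
        for l in range(3):
            for n in range(3):
                sl, sn = slice(l * R, (l + 1) * R), slice(n * R, (n + 1) * R)
                blk = (Phi * (qw * G2[:, l, n])[:, None]).T @ Phi
                blk -= (D * (qw * Jf[:, l, n])[:, None]).T @ Phi
                blk -= (Phi * (qw * Jf[:, n, l])[:, None]).T @ D
                if l == n:
                    blk += prob.DtWD
                GN[sl, sn] += 2.0 * lam * blk
    return val, grad, GN


def _solve_genotype(prob, Hbc, theta, lam, x0, gtol, max_iter):
    """Damped (Levenberg-Marquardt) Gauss-Newton on one genotype block.

    Stops on the relative gradient norm, on a negligible predicted
    decrease of the local quadratic model, or when damping cannot produce
    an acceptable step.
    """
    x = x0.copy()
    val, grad, GN = _genotype_objective(prob, Hbc, theta, lam, x)
    nu = 1e-9
    I = np.eye(len(x))
    it = 0
    for it in range(max_iter):
        if np.linalg.norm(grad, np.inf) <= gtol * (1.0 + abs(val)):
            return x, val, it, True
        accepted = False
        for _ in range(16):
            try:
                step = np.linalg.solve(GN + nu * I, -grad)
            except np.linalg.LinAlgError:
                nu = max(nu * 10.0, 1e-6)
                continue
            pred = -(grad @ step + 0.5 * step @ (GN @ step))
            if pred <= 1e-15 * (1.0 + abs(val)):
                # at the quadratic model's floor; nothing left to gain
                ok = np.linalg.norm(grad, np.inf) <= 1e-3 * (1.0 + abs(val))
                return x, val, it, ok
            xn = x + step
            vn, gn, GNn = _genotype_objective(prob, Hbc, theta, lam, xn)
            if np.isfinite(vn) and vn <= val:
                x, val, grad, GN = xn, vn, gn, GNn
                nu = max(nu / 3.0, 1e-12)
                accepted = True
                break
            nu *= 10.0
        if not accepted:
            break
    ok = np.linalg.norm(grad, np.inf) <= 1e-3 * (1.0 + abs(val))
    return x, val, it + 1, ok


def inner_fit(
    panel,
    weights,
    theta,
    basis: BasisSystem,
    lam: float = 1e2,
    sigma2=None,
    quad_points: int = 5,
    c0: np.ndarray | None = None,
    gtol: float = 1e-8,
    max_iter: int = 100,
    problem: "_InnerProblem | None" = None,
) -> Coefficients:
    """Minimize the ODE-penalized criterion U(c|Theta) over basis coefficients.

    Parameters
    ----------
    panel : PhenotypePanel
        Longitudinal leaf/stem/root observations per line.
    weights : (n, J) array
        Conditional genotype probabilities (columns sum the mixture);
        a single column of ones for the no-QTL model.
    theta : sequence of OdeParams, length J
        Structural parameters fixing the penalty's target dynamics.
    lam : float
        Penalty weight; 0 gives the (rank-deficient, minimum-norm)
        weighted least-squares spline fit.
    sigma2 : (3,) array, optional
        Residual variances weighting the traits; defaults to ones.
    c0 : (J, R, 3) array, optional
        Warm start for the Gauss-Newton iteration.

    Because both the data term and the penalty decompose over genotypes,
    each genotype's (R x 3) block is solved independently.
    """
    if lam < 0:
        raise ValueError("penalty weight lambda must be non-negative")
    theta = list(theta)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    J = weights.shape[1]
    if len(theta) != J:
        raise ValueError("one OdeParams per genotype column required")
    if sigma2 is None:
        sigma2 = np.ones(3)
    prob = problem if problem is not None else _InnerProblem(panel, weights, basis, sigma2, quad_points)
    prob.sigma2 = np.asarray(sigma2, dtype=float)
    R = prob.R

    C = np.empty((J, R, 3))
    total, iters, all_ok = 0.0, 0, True
    for j in range(J):
        Hbc = prob.data_quadratics(j)
        if c0 is not None:
            x0 = np.asarray(c0[j]).T.reshape(-1)
        else:
            x0 = prob.smooth_start(j)
        if lam == 0:
            H, b, const = Hbc
            x = np.linalg.lstsq(H, b, rcond=None)[0]
            val = const - 2.0 * b @ x + x @ (H @ x)
            it, ok = 0, True
        else:
            x, val, it, ok = _solve_genotype(prob, Hbc, theta[j], lam, x0, gtol, max_iter)
        C[j] = x.reshape(3, R).T
        total += val
        iters = max(iters, it)
        all_ok = all_ok and ok
    coef = Coefficients(c=C, basis=basis, criterion=total, n_iter=iters, converged=all_ok)
    if not all_ok:
        raise InnerFitError("inner Gauss-Newton did not converge", C)
    return coef
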