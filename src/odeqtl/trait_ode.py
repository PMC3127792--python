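"""Allometric biomass-partitioning ODE system and its numerical solution.

Whole-plant growth is modelled as the coordination of three organ pools —
leaf ``M_L``, stem ``M_S`` and root ``M_R`` (grams dry weight) — each
gaining biomass as a power law of whole-plant biomass
``W = M_L + M_S + M_R`` (allometric scaling), with first-order loss terms
for the senescing organs:

    dM_L/dt = alpha_L * W**beta_L - gamma_L * M_L
    dM_S/dt = alpha_S * W**beta_S
    dM_R/dt = alpha_R * W**beta_R - gamma_R * M_R

``alpha`` is the allometric constant (g^(1-beta)/day), ``beta`` the
dimensionless scaling exponent, and ``gamma`` (1/day) the elimination rate
of ageing leaves and roots; the stem only accumulates. In the QTL model
each genotype at a locus carries its own parameter vector, so genetic
variation acts on the design of the growth system rather than on a single
trait value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.integrate import solve_ivp


class OdeSolverError(RuntimeError):
    """Raised when the trajectory integrator fails; carries the parameters."""

    def __init__(self, message: str, params: "OdeParams"):
        super().__init__(f"{message} (params={params})")
        self.params = params


@dataclass(frozen=True)
class OdeParams:
    """One genotype's structural parameters plus auxiliary initial state.

    The eight structural parameters are what the mapping model estimates
    and tests; the three initial biomasses anchor trajectory solutions at
    the first observation age and are auxiliary (the spline-based
    estimator does not use them).
    """

    alpha_L: float
    beta_L: float
    gamma_L: float
    alpha_S: float
    beta_S: float
    alpha_R: float
    beta_R: float
    gamma_R: float
    init_L: float = 1.5
    init_S: float = 0.5
    init_R: float = 0.5

    STRUCTURAL: tuple = (
        "alpha_L", "beta_L", "gamma_L", "alpha_S",
        "beta_S", "alpha_R", "beta_R", "gamma_R",
    )

    def __post_init__(self):
        for name in ("alpha_L", "alpha_S", "alpha_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma_L", "gamma_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("init_L", "init_S", "init_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("beta_L", "beta_S", "beta_R"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def structural(self) -> np.ndarray:
        """The 8 structural parameters in canonical order."""
        return np.array([getattr(self, k) for k in self.STRUCTURAL])

    @property
    def init_state(self) -> np.ndarray:
        return np.array([self.init_L, self.init_S, self.init_R])

    @classmethod
    def from_structural(cls, vec, init_state=(1.5, 0.5, 0.5)) -> "OdeParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (8,):
            raise ValueError("structural parameter vector must have length 8")
        iL, iS, iR = init_state
        return cls(*vec, init_L=iL, init_S=iS, init_R=iR)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_init(self, init_state) -> "OdeParams":
        iL, iS, iR = init_state
        return replace(self, init_L=iL, init_S=iS, init_R=iR)


def ode_rhs(state, params: OdeParams) -> np.ndarray:
    """Organ growth rates (g/day) at a (leaf, stem, root) biomass state."""
    state = np.asarray(state, dtype=float)
    if np.any(state <= 0):
        raise ValueError(f"organ biomasses must be positive, got {state}")
    mL, mS, mR = state
    W = state.sum()
    return np.array([
        params.alpha_L * W ** params.beta_L - params.gamma_L * mL,
        params.alpha_S * W ** params.beta_S,
        params.alpha_R * W ** params.beta_R - params.gamma_R * mR,
    ])


@dataclass(frozen=True)
class Trajectory:
    """Solved organ-biomass curves on a time grid (days)."""

    times: np.ndarray
    M_L: np.ndarray
    M_S: np.ndarray
    M_R: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return self.M_L + self.M_S + self.M_R

    def organs(self) -> np.ndarray:
        """(m, 3) array of (leaf, stem, root) biomass."""
        return np.column_stack([self.M_L, self.M_S, self.M_R])

    def to_frame(self, genotype: str = ""):
        import pandas as pd

        df = pd.DataFrame({
            "time": self.times, "M_L": self.M_L,
            "M_S": self.M_S, "M_R": self.M_R, "W": self.W,
        })
        if genotype:
            df.insert(0, "genotype", genotype)
        return df


def solve_trajectory(
    params: OdeParams,
    times,
    t0: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the growth system and return it on the requested grid.

    Adaptive Runge-Kutta (RK45) by default with an automatic LSODA
    retry — the root elimination rate can exceed 2/day, giving a fast
    initial transient. Failure raises :class:`OdeSolverError` rather than
    returning NaNs.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-D grid")
    if t0 is None:
        t0 = float(times[0])
    if times[0] < t0:
        raise ValueError("requested times precede t0")

    y0 = params.init_state

    def f(t, y):
        y = np.maximum(y, 1e-12)  # guard powers against solver overshoot
        W = y.sum()
        return [
            params.alpha_L * W ** params.beta_L - params.gamma_L * y[0],
            params.alpha_S * W ** params.beta_S,
            params.alpha_R * W ** params.beta_R - params.gamma_R * y[2],
        ]

    for method in ("RK45", "LSODA"):
        sol = solve_ivp(
            f, (t0, float(times[-1])), y0, t_eval=times,
            method=method, rtol=rtol, atol=atol, dense_output=False,
        )
        if sol.success and np.all(np.isfinite(sol.y)):
            return Trajectory(times=times, M_L=sol.y[0], M_S=sol.y[1], M_R=sol.y[2])
    raise OdeSolverError(f"integration failed: {sol.message}", params)


def partition_fractions(traj: Trajectory) -> np.ndarray:
    """(m, 3) biomass allocation fractions (leaf, stem, root); rows sum to 1."""
    W = traj.W
    if np.any(W == 0):
        raise ValueError("whole-plant biomass is zero at some time; fractions undefined")
    return traj.organs() / W[:, None]
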