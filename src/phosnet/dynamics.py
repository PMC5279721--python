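"""First-order phosphorylation dynamics.

A protein Y is reversibly phosphorylated by a kinase with activity rate k
(amount per unit time) and de-phosphorylated by a phosphatase with
activity rate p (per unit time). When the unphosphorylated pool is far
larger than the phosphorylated form — the usual situation in vivo — Y is
not rate-limiting and the phosphorylated level Y_p follows the linear
balance

    dY_p/dt = k - p * Y_p

with steady state Y_p* = k / p and, starting from Y_p(0) = 0, the closed
form Y_p(t) = (k/p) * (1 - exp(-p t)). The response time t_1/2 at which
Y_p reaches half its steady state is ln(2)/p: it depends only on the
phosphatase rate. Doubling k and halving p both double the steady state,
but only the phosphatase change slows the response — the quantitative
argument for keeping erasers constitutive and tuning writers.

Units are abstract (rates per unit time); the model is the linear
approximation, with no Michaelis-Menten saturation or substrate
depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DynamicsScenario",
    "Trajectory",
    "steady_state",
    "response_time",
    "analytic_trajectory",
    "numeric_trajectory",
    "half_rise_time",
    "compare_scenarios",
]


def steady_state(k: float, p: float) -> float:
    """Steady-state phosphorylated level k / p."""
    if p <= 0:
        raise ValueError(f"phosphatase rate p must be > 0, got {p}")
    if k < 0:
        raise ValueError(f"kinase rate k must be >= 0, got {k}")
    return k / p


def response_time(p: float) -> float:
    """Time to reach half the steady state, ln(2)/p. Independent of k."""
    if p <= 0:
        raise ValueError(f"phosphatase rate p must be > 0, got {p}")
    return math.log(2.0) / p


@dataclass(frozen=True)
class DynamicsScenario:
    """One (k, p) rate pair with its derived steady state and t_1/2."""

    k: float
    p: float
    label: str = ""

    def __post_init__(self) -> None:
        steady_state(self.k, self.p)  # validates

    @property
    def steady_state(self) -> float:
        return self.k / self.p

    @property
    def t_half(self) -> float:
        return response_time(self.p)


@dataclass(frozen=True)
class Trajectory:
    """Time grid and phosphorylated-protein levels, analytic or numeric."""

    t: np.ndarray
    y: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        if self.t.shape != self.y.shape:
            raise ValueError("time grid and values differ in length")


def _check_grid(t_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least two points")
    if t[0] != 0.0:
        raise ValueError(f"time grid must start at 0, got {t[0]}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    return t


def analytic_trajectory(
    scenario: DynamicsScenario, t_grid: Sequence[float]
) -> Trajectory:
    """Closed-form accumulation from Y_p(0) = 0:
    Y_p(t) = (k/p) (1 - exp(-p t))."""
    t = _check_grid(t_grid)
    y = scenario.steady_state * (1.0 - np.exp(-scenario.p * t))
    return Trajectory(t, y, "analytic")


def _rk4_step(y: float, h: float, k: float, p: float) -> float:
    f = lambda v: k - p * v
    k1 = f(y)
    k2 = f(y + 0.5 * h * k1)
    k3 = f(y + 0.5 * h * k2)
    k4 = f(y + h * k3)
    return y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def _integrate(scenario: DynamicsScenario, t: np.ndarray, y0: float,
               substeps: int) -> np.ndarray:
    y = np.empty_like(t)
    y[0] = cur = y0
    for i in range(1, t.size):
        h = (t[i] - t[i - 1]) / substeps
        for _ in range(substeps):
            cur = _rk4_step(cur, h, scenario.k, scenario.p)
        y[i] = cur
    return y


def numeric_trajectory(
    scenario: DynamicsScenario,
    t_grid: Sequence[float],
    y0: float = 0.0,
    tol: float = 1e-9,
) -> Trajectory:
    """Fixed-step 4th-order Runge-Kutta integration of dY_p/dt = k - p Y_p.

    The step is refined by halving until a further halving changes no
    grid value by more than ``tol``. Supports arbitrary nonnegative
    initial conditions (the closed form covers only y0 = 0).
    """
    t = _check_grid(t_grid)
    if y0 < 0:
        raise ValueError(f"initial value must be >= 0, got {y0}")
    bound = 10 * max(scenario.steady_state, y0, 1.0)
    substeps = 1
    y = _integrate(scenario, t, y0, substeps)
    for _ in range(24):
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > bound:
            raise RuntimeError("numeric integration diverged")
        substeps *= 2
        y_half = _integrate(scenario, t, y0, substeps)
        if np.max(np.abs(y_half - y)) <= tol:
            return Trajectory(t, y_half, "numeric")
        y = y_half
    raise RuntimeError("step refinement failed to converge")


def half_rise_time(traj: Trajectory, steady: float) -> float:
    """Empirical t_1/2: linear interpolation of the first crossing of
    half the steady state."""
    target = steady / 2.0
    above = np.nonzero(traj.y >= target)[0]
    if above.size == 0:
        raise ValueError("trajectory never reaches half the steady state")
    i = above[0]
    if i == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[i - 1], traj.t[i]
    y0, y1 = traj.y[i - 1], traj.y[i]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def compare_scenarios(
    baseline: DynamicsScenario,
    variant: DynamicsScenario,
    n_grid: int = 2001,
) -> dict:
    """Fold changes between two rate scenarios.

    Returns the steady-state fold change and response-time ratio
    (variant over baseline), each both from the closed forms and from
    numerically integrated trajectories.
    """
    horizon = 12.0 * max(baseline.t_half, variant.t_half)
    t = np.linspace(0.0, horizon, n_grid)
    out = {
        "steady_state_fold": variant.steady_state / baseline.steady_state,
        "t_half_ratio": variant.t_half / baseline.t_half,
    }
    tb = numeric_trajectory(baseline, t)
    tv = numeric_trajectory(variant, t)
    out["steady_state_fold_trajectory"] = float(tv.y[-1] / tb.y[-1])
    out["t_half_ratio_trajectory"] = (
        half_rise_time(tv, variant.steady_state)
        / half_rise_time(tb, baseline.steady_state)
    )
    return out
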