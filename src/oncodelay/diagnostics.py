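"""Trajectory-level certificates and summaries.

The subthreshold regime (``R0 < 1``) admits the Lyapunov functional

    V(t) = b y(t) + v(t) + b sum_i beta_i integral_{t-tau_i}^{t} x(s) v(s) ds,

which is nonincreasing along solutions and certifies global convergence
to the therapy-failure state ``E1 = (K, 0, 0)``.  This module evaluates
``V`` on computed trajectories (the integral by adaptive quadrature on
the dense representation), checks its monotonicity on a grid, locates
the tumor-eradication time ``x + y <= threshold`` (one cell in model
units), and condenses a run into a scenario summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .hopf import oscillation_metrics
from .model import ModelParameters, State, basic_reproduction_number, equilibria
from .solver import Trajectory

__all__ = [
    "LyapunovSample",
    "MonotoneReport",
    "ScenarioSummary",
    "lyapunov_value",
    "lyapunov_decrease_bound",
    "lyapunov_monotone_check",
    "eradication_time",
    "summarize",
]

#: default eradication threshold (model units): the conventional
#: one-cell elimination level of the source scenarios
ERADICATION_THRESHOLD = 1.0

#: terminal distance (relative to K) below which a run counts as converged
CONVERGENCE_REL_TOL = 1e-3


@dataclass(frozen=True)
class LyapunovSample:
    t: float
    V: float
    V_dot: float


@dataclass(frozen=True)
class MonotoneReport:
    """Outcome of the grid monotonicity check on ``V``.

    ``verdict`` is ``"pass"``/``"fail"`` for ``R0 < 1`` runs and
    ``"not applicable"`` otherwise (the theory makes no claim there).
    ``worst_increase`` is the largest observed rise between consecutive
    grid points (0 when monotone).
    """

    verdict: Literal["pass", "fail", "not applicable"]
    worst_increase: float
    r0: float


@dataclass(frozen=True)
class ScenarioSummary:
    terminal_state: State
    converged_to: Literal["E0", "E1", "Estar", "cycle", "none"]
    eradication_time: Optional[float]
    tumor_load_min: float
    tumor_load_max: float


def _xv_integral(traj: Trajectory, t0: float, t1: float) -> float:
    if t1 <= t0:
        return 0.0
    val, _ = quad(
        lambda s: float(traj(s)[0] * traj(s)[2]),
        t0,
        t1,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return val


def lyapunov_value(
    params: ModelParameters, traj: Trajectory, t: float
) -> LyapunovSample:
    """Evaluate ``V`` and a numeric estimate of its time derivative.

    Requires the full memory window ``[t - tau_max, t]`` to lie inside
    the trajectory span.  ``V_dot`` is a central difference with step
    1e-3 days (one-sided at the span ends).
    """
    tau_max = params.tau_max
    if t - tau_max < traj.t_min or t > traj.t_max:
        raise ValueError(
            f"Lyapunov window [{t - tau_max}, {t}] outside span {traj.span}"
        )

    def V(tt: float) -> float:
        state = traj(tt)
        total = params.b * state[1] + state[2]
        for term in params.transmission:
            if term.tau > 0.0:
                total += params.b * term.beta * _xv_integral(
                    traj, tt - term.tau, tt
                )
        return float(total)

    h = 1e-3
    lo_ok = t - h - tau_max >= traj.t_min
    hi_ok = t + h <= traj.t_max
    v0 = V(t)
    if lo_ok and hi_ok:
        v_dot = (V(t + h) - V(t - h)) / (2.0 * h)
    elif hi_ok:
        v_dot = (V(t + h) - v0) / h
    elif lo_ok:
        v_dot = (v0 - V(t - h)) / h
    else:  # pragma: no cover - degenerate span
        v_dot = 0.0
    return LyapunovSample(t=float(t), V=v0, V_dot=float(v_dot))


def lyapunov_decrease_bound(params: ModelParameters, v_component: float) -> float:
    """Algebraic upper bound on ``dV/dt``: ``beta K b (1 - 1/R0) v``.

    Exposed for cross-checking the numeric derivative; negative whenever
    ``R0 < 1`` and virus is present.
    """
    from .model import beta_total

    r0 = basic_reproduction_number(params)
    return float(
        beta_total(params) * params.K * params.b * (1.0 - 1.0 / r0) * v_component
    )


def lyapunov_monotone_check(
    params: ModelParameters, traj: Trajectory, grid: Sequence[float]
) -> MonotoneReport:
    """Check that ``V`` is nonincreasing across the grid (``R0 < 1`` only).

    Tolerance: rises up to ``1e-8 * max(V)`` are attributed to
    quadrature/solver noise and ignored.
    """
    r0 = basic_reproduction_number(params)
    if r0 >= 1.0:
        return MonotoneReport(verdict="not applicable", worst_increase=np.nan, r0=r0)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise ValueError("grid must contain at least two times")
    values = np.array([lyapunov_value(params, traj, t).V for t in grid])
    rises = np.diff(values)
    worst = float(max(0.0, np.max(rises)))
    tol = 1e-8 * max(np.max(values), 1e-300)
    verdict = "pass" if worst <= tol else "fail"
    return MonotoneReport(verdict=verdict, worst_increase=worst, r0=r0)


def eradication_time(
    traj: Trajectory, threshold: float = ERADICATION_THRESHOLD
) -> Optional[float]:
    """First time the total tumor load ``x + y`` drops to the threshold.

    Scans a dense grid and refines the first crossing by bisection on
    the dense trajectory; ``None`` when the load never reaches the
    threshold.
    """
    if not (threshold > 0.0):
        raise ValueError("threshold must be > 0")
    times = np.linspace(traj.t_min, traj.t_max, 4001)
    load = traj(times)[:, :2].sum(axis=1)
    below = load <= threshold
    if not below.any():
        return None
    first = int(np.argmax(below))
    if first == 0:
        return float(traj.t_min)
    f = lambda t: float(traj(t)[:2].sum()) - threshold
    return float(brentq(f, times[first - 1], times[first], xtol=1e-10))


def summarize(params: ModelParameters, traj: Trajectory) -> ScenarioSummary:
    """Condense a run: terminal state, attractor, eradication, load range."""
    eq = equilibria(params)
    terminal = traj.terminal_state()
    term_arr = np.asarray(terminal, dtype=float)

    converged: str = "none"
    tol = CONVERGENCE_REL_TOL * params.K
    candidates = [("E0", eq.E0), ("E1", eq.E1)]
    if eq.Estar is not None:
        candidates.append(("Estar", eq.Estar))
    for name, point in candidates:
        if np.max(np.abs(term_arr - np.asarray(point))) < tol:
            converged = name
            break
    if converged == "none":
        window = (0.5 * traj.t_max, traj.t_max)
        metrics = oscillation_metrics(traj, "x", window=window)
        if metrics.n_peaks >= 3 and metrics.amplitude is not None:
            if metrics.amplitude > CONVERGENCE_REL_TOL * params.K:
                converged = "cycle"

    times = np.linspace(max(0.0, traj.t_min), traj.t_max, 4001)
    load = traj(times)[:, :2].sum(axis=1)
    return ScenarioSummary(
        terminal_state=terminal,
        converged_to=converged,  # type: ignore[arg-type]
        eradication_time=eradication_time(traj),
        tumor_load_min=float(np.min(load)),
        tumor_load_max=float(np.max(load)),
    )
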