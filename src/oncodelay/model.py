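"""Core model: parameters, state, right-hand side, R0 and equilibria.

The model describes oncolytic virotherapy of a tumor with three
populations, all in units of 10^6 (cells or virions):

* ``x`` — uninfected tumor cells, growing logistically toward the
  carrying capacity ``K`` and lost to free-virus infection (``beta*x*v``)
  and to cell-to-cell fusion with infected cells (``rho*x*y``),
* ``y`` — infected tumor cells, recruited through the viral lytic cycle
  and dying at rate ``delta``,
* ``v`` — free virions, released at burst size ``b`` per lysed cell and
  cleared at rate ``gamma`` (plus absorption into cells, ``beta*x*v``).

The lytic cycle takes time: new infected cells appearing at time ``t``
derive from encounters at earlier times, so the infection influx is a sum
of delayed terms ``beta_i * x(t - tau_i) * v(t - tau_i)``.  Each
:class:`TransmissionTerm` carries one ``(beta_i, tau_i)`` pair; a single
``tau = 0`` term represents instantaneous transmission.  The total
infection rate constant ``beta`` that appears in the ``x`` and ``v``
equations is the sum of all ``beta_i``, including any instantaneous term.

The basic reproduction number

    R0 = beta * K * b / (beta * K + gamma)

counts new virions produced per virion introduced into a fully
susceptible tumor; the virus persists only for ``R0 > 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "TransmissionTerm",
    "ModelParameters",
    "State",
    "EquilibriumSet",
    "beta_total",
    "basic_reproduction_number",
    "burst_size_for_r0",
    "with_target_r0",
    "equilibria",
    "rhs",
    "equilibrium_residual",
    "params_to_dict",
    "params_from_dict",
]

#: residual bound (max norm) enforced on every closed-form equilibrium
EQUILIBRIUM_RESIDUAL_TOL = 1e-9


class State(NamedTuple):
    """Population state ``(x, y, v)`` in units of 10^6 cells / virions."""

    x: float
    y: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class TransmissionTerm:
    """One delayed infection channel ``beta * x(t - tau) * v(t - tau)``.

    ``beta`` is the rate constant (per (10^6 virions)·day), ``tau`` the
    lytic-cycle stage delay in days.  ``tau = 0`` encodes instantaneous
    transmission.
    """

    beta: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.beta >= 0.0):
            raise ValueError(f"transmission beta must be >= 0, got {self.beta}")
        if not (self.tau >= 0.0):
            raise ValueError(f"transmission tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the delayed virotherapy model.

    Parameters
    ----------
    r : logistic growth rate of uninfected tumor cells (per day).
    K : carrying capacity / maximal tumor size (10^6 cells).
    rho : cell-to-cell fusion (syncytium formation) rate constant.
    delta : infected-cell death rate (per day).
    b : burst size — virions released per lysed infected cell.
    gamma : free-virus clearance rate (per day); zero is allowed.
    transmission : ordered ``(beta_i, tau_i)`` terms with strictly
        increasing delays; at most one term may have ``tau = 0``.
    """

    r: float
    K: float
    rho: float
    delta: float
    b: float
    gamma: float
    transmission: tuple[TransmissionTerm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transmission", tuple(self.transmission))
        for name in ("r", "K", "rho", "delta", "b"):
            val = getattr(self, name)
            if not (val > 0.0):
                raise ValueError(f"parameter {name} must be > 0, got {val}")
        if not (self.gamma >= 0.0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not self.transmission:
            raise ValueError("at least one transmission term is required")
        taus = [t.tau for t in self.transmission]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("transmission delays must be strictly increasing")
        if sum(1 for t in taus if t == 0.0) > 1:
            raise ValueError("at most one transmission term may have tau = 0")
        if not (sum(t.beta for t in self.transmission) > 0.0):
            raise ValueError("total transmission rate must be positive")

    @property
    def tau_max(self) -> float:
        return max(t.tau for t in self.transmission)

    @property
    def delays(self) -> tuple[float, ...]:
        return tuple(t.tau for t in self.transmission)

    @property
    def delayed_terms(self) -> tuple[TransmissionTerm, ...]:
        """Transmission terms with strictly positive delay."""
        return tuple(t for t in self.transmission if t.tau > 0.0)

    @property
    def beta_instantaneous(self) -> float:
        """Rate constant of the ``tau = 0`` channel (0 if absent)."""
        return sum(t.beta for t in self.transmission if t.tau == 0.0)


@dataclass(frozen=True)
class EquilibriumSet:
    """The three steady states of the model.

    ``E0 = (0,0,0)`` is tumor extinction (always unstable), ``E1 =
    (K,0,0)`` is therapy failure with the tumor at carrying capacity, and
    ``Estar`` is the coexistence (endemic) state, present exactly when
    ``R0 > 1``.
    """

    E0: State
    E1: State
    Estar: Optional[State]
    exists_endemic: bool


def beta_total(params: ModelParameters) -> float:
    """Total infection rate constant: sum of all beta_i (delayed and not)."""
    return float(sum(t.beta for t in params.transmission))


def basic_reproduction_number(params: ModelParameters) -> float:
    """R0 = beta*K*b / (beta*K + gamma)."""
    beta = beta_total(params)
    denom = beta * params.K + params.gamma
    if denom <= 0.0:
        raise ValueError("beta*K + gamma must be positive")
    return beta * params.K * params.b / denom


def burst_size_for_r0(params: ModelParameters, target_r0: float) -> float:
    """Burst size ``b`` yielding the requested R0 (``b`` in params ignored).

    Inverts the R0 formula: ``b = R0 * (beta*K + gamma) / (beta*K)``.
    """
    if not (target_r0 > 0.0):
        raise ValueError("target_r0 must be > 0")
    beta = beta_total(params)
    bk = beta * params.K
    if bk <= 0.0:
        raise ValueError("beta*K must be positive to invert R0")
    return float(target_r0 * (bk + params.gamma) / bk)


def with_target_r0(params: ModelParameters, target_r0: float) -> ModelParameters:
    """Return a copy of ``params`` with ``b`` solved from the target R0."""
    return replace(params, b=burst_size_for_r0(params, target_r0))


def rhs(
    params: ModelParameters,
    now: Sequence[float],
    delayed: Sequence[Sequence[float]],
) -> np.ndarray:
    """Model right-hand side.

    ``delayed`` holds one ``(x, y, v)`` state per transmission term, the
    populations at ``t - tau_i``; the entry for a ``tau = 0`` term must be
    the current state.  Only the delayed ``x`` and ``v`` enter the
    infected-cell equation.
    """
    if len(delayed) != len(params.transmission):
        raise ValueError(
            f"expected {len(params.transmission)} delayed states, "
            f"got {len(delayed)}"
        )
    x, y, v = now
    beta = beta_total(params)
    infection = 0.0
    for term, past in zip(params.transmission, delayed):
        infection += term.beta * past[0] * past[2]
    dx = params.r * x * (1.0 - (x + y) / params.K) - beta * x * v - params.rho * x * y
    dy = infection - params.delta * y
    dv = params.b * params.delta * y - params.gamma * v - beta * x * v
    return np.array([dx, dy, dv])


def equilibrium_residual(params: ModelParameters, point: Sequence[float]) -> float:
    """Max-norm of the RHS with all delayed states frozen at ``point``."""
    delayed = [point] * len(params.transmission)
    return float(np.max(np.abs(rhs(params, point, delayed))))


def equilibria(params: ModelParameters) -> EquilibriumSet:
    """Closed-form steady states.

    The endemic point solves the steady-state system directly:
    ``x* = gamma / (beta (b-1))`` from the virus balance, ``y* = beta x*
    v* / delta`` from the infected-cell balance, and ``v*`` from the
    logistic equation.  It is positive exactly when ``R0 > 1``
    (equivalently ``beta*K*(b-1) > gamma``).
    """
    K = params.K
    beta = beta_total(params)
    r, rho, delta, b, gamma = params.r, params.rho, params.delta, params.b, params.gamma

    E0 = State(0.0, 0.0, 0.0)
    E1 = State(K, 0.0, 0.0)

    Estar: Optional[State] = None
    exists = b > 1.0 and K * beta * (b - 1.0) > gamma
    if exists:
        denom = r * gamma + delta * K * beta * (b - 1.0) + rho * K * gamma
        num = K * b * beta - K * beta - gamma
        x_s = gamma / (beta * (b - 1.0))
        y_s = gamma * r * num / (beta * (b - 1.0) * denom)
        v_s = delta * r * num / (beta * denom)
        if x_s > 0.0 and y_s > 0.0 and v_s > 0.0:
            Estar = State(x_s, y_s, v_s)
        else:  # pragma: no cover - guarded by the existence condition
            exists = False

    out = EquilibriumSet(E0=E0, E1=E1, Estar=Estar, exists_endemic=Estar is not None)
    for point in (E0, E1) + ((Estar,) if Estar is not None else ()):
        res = equilibrium_residual(params, point)
        scale = max(1.0, K)
        if res > EQUILIBRIUM_RESIDUAL_TOL * scale:
            raise RuntimeError(
                f"equilibrium residual {res:.3e} exceeds tolerance at {point}"
            )
    return out


# ---------------------------------------------------------------------------
# serialization

def params_to_dict(params: ModelParameters) -> dict:
    """Flat mapping used by YAML/JSON configs (keys are the contract)."""
    return {
        "r": params.r,
        "K": params.K,
        "rho": params.rho,
        "delta": params.delta,
        "b": params.b,
        "gamma": params.gamma,
        "transmission": [
            {"beta": t.beta, "tau": t.tau} for t in params.transmission
        ],
    }


def params_from_dict(data: dict) -> ModelParameters:
    """Build parameters from a flat mapping.

    Either ``b`` or ``r0`` must be present; with ``r0`` the burst size is
    solved so that R0 equals the given value.
    """
    try:
        transmission = tuple(
            TransmissionTerm(beta=float(t["beta"]), tau=float(t["tau"]))
            for t in data["transmission"]
        )
        base = dict(
            r=float(data["r"]),
            K=float(data["K"]),
            rho=float(data["rho"]),
            delta=float(data["delta"]),
            gamma=float(data["gamma"]),
            transmission=transmission,
        )
    except KeyError as exc:
        raise ValueError(f"missing parameter key: {exc}") from exc
    if "b" in data:
        return ModelParameters(b=float(data["b"]), **base)
    if "r0" in data:
        probe = ModelParameters(b=1.0, **base)
        return replace(probe, b=burst_size_for_r0(probe, float(data["r0"])))
    raise ValueError("config must provide either 'b' or 'r0'")
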