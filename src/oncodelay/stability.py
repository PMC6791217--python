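"""Linear stability analysis at the steady states.

Two equilibria matter: the therapy-failure state ``E1 = (K, 0, 0)`` and
the endemic state ``E*``.  At ``E1`` the delay-free Jacobian factors,
giving three real eigenvalues whose threshold eigenvalue changes sign
exactly at ``R0 = 1``; for arbitrary delays a purely imaginary
characteristic root would have to satisfy a quartic in ``omega`` whose
coefficients are all positive when ``R0 < 1``, which yields a
delay-robustness certificate.

At ``E*`` the characteristic equation is transcendental,

    lambda^3 + A lambda^2 + Bt lambda + C
        + sum_i beta_i e^(-lambda tau_i) (D lambda + E) = 0,

with the coefficients obtained here from the determinant expansion of
the linearization (the delayed sum enters the Jacobian affinely, so A,
Bt, C come from the characteristic polynomial of the sum-free part and
D, E from the affine increment — an exact extraction, not a fit).  The
delay-free cubic is tested by the Routh--Hurwitz criterion; for the
delayed system, positivity of the crossing-polynomial coefficients
``K1, K2(omega), K3(omega)`` over a frequency grid certifies that no
root can reach the imaginary axis at any delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .model import (
    ModelParameters,
    State,
    basic_reproduction_number,
    beta_total,
    equilibria,
)

__all__ = [
    "DFESpectrum",
    "CharacteristicData",
    "RouthHurwitzReport",
    "DelayRobustnessCertificate",
    "EndemicDelayCertificate",
    "jacobian",
    "characteristic_value",
    "dfe_spectrum_tau0",
    "dfe_delay_robustness",
    "endemic_char_coefficients",
    "endemic_tau0_stability",
    "endemic_delay_condition",
    "default_omega_grid",
]

#: any Routh-Hurwitz quantity closer to zero than this is called marginal
MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class DFESpectrum:
    """Eigenvalues of the delay-free Jacobian at ``E1 = (K,0,0)``.

    ``lambda1 = -r`` always; ``lambda2 <= lambda3`` are the roots of the
    quadratic factor with discriminant ``Delta``; ``lambda3`` has the
    sign of ``R0 - 1``.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    Delta: float


@dataclass(frozen=True)
class CharacteristicData:
    """Coefficients of the endemic characteristic equation.

    ``A, B_tilde, C`` form the delay-free cubic part, ``D, E`` the
    common linear factor of the delayed terms.  ``beta0`` is the
    instantaneous transmission rate; for the single-positive-delay case
    the crossing-polynomial constants ``K1, K2, K3`` of
    ``omega^6 + K1 omega^4 + K2 omega^2 + K3`` are filled in, otherwise
    they are ``None`` (use :func:`endemic_delay_condition` for the
    omega-dependent general form).
    """

    A: float
    B_tilde: float
    C: float
    D: float
    E: float
    beta0: float
    K1: Optional[float] = None
    K2: Optional[float] = None
    K3: Optional[float] = None


@dataclass(frozen=True)
class RouthHurwitzReport:
    """Routh--Hurwitz test of the delay-free endemic cubic.

    ``b1, b2, b3`` are the coefficients of
    ``lambda^3 + b1 lambda^2 + b2 lambda + b3`` obtained by setting all
    delays to zero; ``H2 = b1*b2 - b3``.  All four positive means every
    root has negative real part.
    """

    b1: float
    b2: float
    b3: float
    H2: float
    verdict: Literal["stable", "unstable", "marginal"]


@dataclass(frozen=True)
class DelayRobustnessCertificate:
    """No-imaginary-crossing certificate for ``E1`` at arbitrary delays.

    A purely imaginary root requires
    ``omega^4 + a1 omega^2 + a2(omega) + a3 = 0``; since ``a1 > 0`` and
    ``a2(omega) >= 0`` always, positivity of ``a3`` (i.e. ``R0 < 1``)
    rules such roots out.  ``a2_min`` records the grid minimum of the
    cross-delay term for inspection; ``grid`` semantics: the check is a
    sufficient condition verified pointwise on the supplied frequencies.
    """

    a1: float
    a2_min: float
    a3: float
    r0: float
    issued: bool


@dataclass(frozen=True)
class EndemicDelayCertificate:
    """Grid-checked delay-independent stability condition at ``E*``.

    Issued when the delay-free verdict is stable and ``K1`` and the grid
    minima of ``K2(omega)``, ``K3(omega)`` are all positive — then the
    characteristic roots can never reach the imaginary axis, so ``E*``
    stays locally asymptotically stable for every admissible delay
    vector.
    """

    K1: float
    K2_min: float
    K3_min: float
    tau0_verdict: str
    issued: bool


def _equilibrium_point(params: ModelParameters, which: str) -> State:
    eq = equilibria(params)
    if which == "E1":
        return eq.E1
    if which == "Estar":
        if eq.Estar is None:
            raise ValueError("endemic equilibrium does not exist (R0 <= 1)")
        return eq.Estar
    if which == "E0":
        return eq.E0
    raise ValueError(f"unknown equilibrium {which!r}")


def jacobian(params: ModelParameters, point: Sequence[float], S: complex) -> np.ndarray:
    """Linearization at ``point`` with the delayed sum replaced by ``S``.

    ``S`` stands for ``sum_i beta_i e^(-lambda tau_i)``; passing the
    total ``beta`` gives the delay-free Jacobian, ``0`` isolates the
    delay-free part of the characteristic function.
    """
    x, y, v = point
    r, K, rho, delta, b, gamma = (
        params.r,
        params.K,
        params.rho,
        params.delta,
        params.b,
        params.gamma,
    )
    beta = beta_total(params)
    return np.array(
        [
            [
                r * (1.0 - (2.0 * x + y) / K) - beta * v - rho * y,
                -(r / K) * x - rho * x,
                -beta * x,
            ],
            [S * v, -delta, S * x],
            [-beta * v, b * delta, -gamma - beta * x],
        ],
        dtype=complex,
    )


def characteristic_value(
    params: ModelParameters,
    which: Literal["E1", "Estar"],
    lam: complex,
    delays_active: bool = True,
) -> complex:
    """Exact transcendental characteristic function ``det(lam*I - J(lam))``.

    With ``delays_active`` the delayed sum carries its ``e^(-lam tau_i)``
    factors; without, all delays are treated as zero (``S = beta``).
    Zeros of this function are the characteristic roots.
    """
    point = _equilibrium_point(params, which)
    if delays_active:
        S = sum(t.beta * np.exp(-lam * t.tau) for t in params.transmission)
    else:
        S = beta_total(params)
    J = jacobian(params, point, S)
    return complex(np.linalg.det(lam * np.eye(3) - J))


def dfe_spectrum_tau0(params: ModelParameters) -> DFESpectrum:
    """Closed-form eigenvalues at ``E1`` with all delays zero.

    The characteristic polynomial factors as ``(lambda + r)`` times a
    quadratic; ``Delta = (gamma + beta*K - delta)^2 + 4 beta*K*b*delta``
    is the quadratic's discriminant (always positive, so all eigenvalues
    are real).
    """
    beta = beta_total(params)
    K, delta, gamma, b = params.K, params.delta, params.gamma, params.b
    g = gamma + beta * K
    Delta = (g - delta) ** 2 + 4.0 * beta * K * b * delta
    sq = np.sqrt(Delta)
    lambda1 = -params.r
    lambda2 = (-(g + delta) - sq) / 2.0
    lambda3 = (-(g + delta) + sq) / 2.0
    return DFESpectrum(lambda1=lambda1, lambda2=lambda2, lambda3=lambda3, Delta=Delta)


def default_omega_grid(omega_max: float, n: int = 10_000) -> np.ndarray:
    """Uniform grid on ``(0, omega_max]`` used by the certificates."""
    return np.linspace(omega_max / n, omega_max, n)


def dfe_delay_robustness(
    params: ModelParameters,
    omega_grid: Optional[Sequence[float]] = None,
) -> DelayRobustnessCertificate:
    """Certify that no delay can destabilize ``E1`` when ``R0 < 1``.

    Evaluates ``a1 = (gamma + beta*K)^2 + delta^2``, ``a3 = delta^2
    (gamma + beta*K)^2 (1 - R0^2)`` and the cross-delay term
    ``a2(omega) = 2 (b*K*delta)^2 sum_{i<j} beta_i beta_j
    (1 - cos omega (tau_i - tau_j))`` over the grid.  A certificate is
    issued iff ``R0 < 1`` (then all three quantities are positive /
    nonnegative, so the crossing quartic has no real root).
    """
    beta = beta_total(params)
    K, delta, gamma, b = params.K, params.delta, params.gamma, params.b
    r0 = basic_reproduction_number(params)
    g = gamma + beta * K
    a1 = g**2 + delta**2
    a3 = delta**2 * g**2 * (1.0 - r0**2)

    if omega_grid is None:
        omega_grid = default_omega_grid(10.0 * max(1.0, np.sqrt(a1)))
    omega = np.asarray(omega_grid, dtype=float)
    if omega.size == 0:
        raise ValueError("omega grid must be nonempty")

    terms = params.transmission
    scale = 2.0 * (b * K * delta) ** 2
    a2 = np.zeros_like(omega)
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            dtau = terms[i].tau - terms[j].tau
            a2 += scale * terms[i].beta * terms[j].beta * (
                1.0 - np.cos(omega * dtau)
            )
    a2_min = float(np.min(a2))
    issued = r0 < 1.0 and a1 > 0.0 and a3 > 0.0 and a2_min >= -1e-12
    return DelayRobustnessCertificate(
        a1=float(a1), a2_min=a2_min, a3=float(a3), r0=float(r0), issued=issued
    )


def _char_parts(params: ModelParameters) -> tuple[np.ndarray, float, float]:
    """Cubic coefficients ``[1, A, Bt, C]`` and the affine pair ``(D, E)``.

    ``det(lam*I - J(S))`` is affine in the scalar ``S`` standing for the
    delayed sum, so the sum-free cubic is the characteristic polynomial
    of ``J(0)`` and the increment at ``S = 1`` is exactly ``D lam + E``.
    """
    eq = equilibria(params)
    if eq.Estar is None:
        raise ValueError("endemic equilibrium does not exist (R0 <= 1)")
    point = eq.Estar
    J0 = jacobian(params, point, 0.0).real
    cubic = np.poly(J0)  # [1, A, Bt, C]
    J1 = jacobian(params, point, 1.0).real

    def inc(lam: float) -> float:
        a = np.linalg.det(lam * np.eye(3) - J1)
        b = np.linalg.det(lam * np.eye(3) - J0)
        return float(a - b)

    E = inc(0.0)
    D = inc(1.0) - E
    return cubic, D, E


def endemic_char_coefficients(params: ModelParameters) -> CharacteristicData:
    """Coefficients ``A, Bt, C, D, E`` of the endemic characteristic equation.

    For scenarios with exactly one positive-delay transmission term the
    crossing-polynomial constants are also filled in:

        K1 = A^2 - 2 (Bt + beta0 D)
        K2 = (Bt + beta0 D)^2 - 2 A (C + beta0 E) - (beta1 D)^2
        K3 = (C + beta0 E)^2 - (beta1 E)^2

    where ``beta0`` is the instantaneous rate and ``beta1`` the delayed
    one.  A negative ``K3`` forces a positive crossing frequency and
    hence a Hopf bifurcation at some finite delay.
    """
    cubic, D, E = _char_parts(params)
    A, B_tilde, C = (float(c) for c in cubic[1:])
    beta0 = params.beta_instantaneous

    K1 = K2 = K3 = None
    delayed = params.delayed_terms
    if len(delayed) == 1:
        beta1 = delayed[0].beta
        p = B_tilde + beta0 * D
        q = C + beta0 * E
        K1 = A**2 - 2.0 * p
        K2 = p**2 - 2.0 * A * q - (beta1 * D) ** 2
        K3 = q**2 - (beta1 * E) ** 2
    return CharacteristicData(
        A=A, B_tilde=B_tilde, C=C, D=float(D), E=float(E), beta0=float(beta0),
        K1=K1, K2=K2, K3=K3,
    )


def _verdict(values: Sequence[float]) -> str:
    if any(abs(v) < MARGINAL_TOL for v in values):
        return "marginal"
    return "stable" if all(v > 0.0 for v in values) else "unstable"


def endemic_tau0_stability(params: ModelParameters) -> RouthHurwitzReport:
    """Routh--Hurwitz verdict on the delay-free cubic at ``E*``.

    Setting all delays to zero collapses the characteristic equation to
    ``lambda^3 + A lambda^2 + (Bt + beta*D) lambda + (C + beta*E) = 0``
    with ``beta`` the total transmission rate.
    """
    coeffs = endemic_char_coefficients(params)
    beta = beta_total(params)
    b1 = coeffs.A
    b2 = coeffs.B_tilde + beta * coeffs.D
    b3 = coeffs.C + beta * coeffs.E
    H2 = b1 * b2 - b3
    return RouthHurwitzReport(
        b1=b1, b2=b2, b3=b3, H2=H2, verdict=_verdict([b1, b2, b3, H2])
    )


def endemic_delay_condition(
    params: ModelParameters,
    omega_grid: Optional[Sequence[float]] = None,
) -> EndemicDelayCertificate:
    """Delay-independent stability check at ``E*`` for any number of delays.

    A purely imaginary root ``i omega`` must satisfy
    ``omega^6 + K1 omega^4 + K2(omega) omega^2 + K3(omega) = 0`` with

        K2(omega) = (Bt + beta0 D)^2 - 2A(C + beta0 E) - (sum_d beta_d)^2 D^2
                    + 2 D^2 sum_{i<j} beta_i beta_j (1 - cos omega(tau_i - tau_j))
        K3(omega) = (C + beta0 E)^2 - (sum_d beta_d)^2 E^2
                    + 2 E^2 sum_{i<j} beta_i beta_j (1 - cos omega(tau_i - tau_j))

    (sums over the positive-delay terms).  Positivity of ``K1`` and of
    both grid minima, together with a stable delay-free verdict,
    certifies local asymptotic stability at every delay.
    """
    coeffs = endemic_char_coefficients(params)
    report = endemic_tau0_stability(params)
    delayed = params.delayed_terms

    p = coeffs.B_tilde + coeffs.beta0 * coeffs.D
    q = coeffs.C + coeffs.beta0 * coeffs.E
    beta_d = sum(t.beta for t in delayed)
    K1 = coeffs.A**2 - 2.0 * p

    if omega_grid is None:
        omega_grid = default_omega_grid(
            10.0 * max(1.0, coeffs.A, np.sqrt(abs(K1)))
        )
    omega = np.asarray(omega_grid, dtype=float)
    if omega.size == 0:
        raise ValueError("omega grid must be nonempty")

    cross = np.zeros_like(omega)
    for i in range(len(delayed)):
        for j in range(i + 1, len(delayed)):
            dtau = delayed[i].tau - delayed[j].tau
            cross += 2.0 * delayed[i].beta * delayed[j].beta * (
                1.0 - np.cos(omega * dtau)
            )
    K2 = p**2 - 2.0 * coeffs.A * q - (beta_d * coeffs.D) ** 2 + coeffs.D**2 * cross
    K3 = q**2 - (beta_d * coeffs.E) ** 2 + coeffs.E**2 * cross

    K2_min = float(np.min(K2))
    K3_min = float(np.min(K3))
    issued = (
        report.verdict == "stable"
        and K1 > 0.0
        and K2_min > 0.0
        and K3_min > 0.0
    )
    return EndemicDelayCertificate(
        K1=float(K1),
        K2_min=K2_min,
        K3_min=K3_min,
        tau0_verdict=report.verdict,
        issued=issued,
    )
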