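"""Closed-form Fisher-KPP machinery.

The Fisher-KPP equation ``u_t = D u_xx + rho u (1 - u)`` admits travelling
wave fronts.  In a co-moving frame travelling at the special dimensionless
speed ``v = 5/sqrt(6)`` the front has the exact sigmoid profile

    U(x) = (1 + exp(x / sqrt(6)))**-2,

which is invertible on the open amplitude range (0, 1).  Substituting the
inverse into the analytic gradient yields an amplitude-only expression for
the advective flux of the equilibrated front,

    p(u) = |v| * sqrt(2/3) * (1 - sqrt(u)) * u,

the *stationalization penalty*: it replaces the co-moving advection term
``v . grad u`` and turns the forward growth model into a stationary
boundary-value problem.  Everything in this module is a pure function of
dimensionless quantities; the solvers and diagnostics consume it.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

__all__ = [
    "SQRT6",
    "SQRT_2_3",
    "ANALYTIC_WAVE_SPEED",
    "NondimScaling",
    "WaveParams",
    "limit_profile",
    "limit_gradient",
    "limit_curvature",
    "limit_inverse",
    "penalty",
    "effective_reaction",
    "positivity_guard",
    "comoving_residual",
    "fit_wave_speed",
    "interior_reaction_root",
]

# Closed-form constants are derived from library square roots, never from
# truncated decimal literals.
SQRT6: float = float(np.sqrt(6.0))
SQRT_2_3: float = float(np.sqrt(2.0 / 3.0))
#: Wave speed of the exactly solvable co-moving front, 5/sqrt(6) ~ 2.0412.
ANALYTIC_WAVE_SPEED: float = 5.0 / SQRT6


@dataclasses.dataclass(frozen=True)
class NondimScaling:
    """Nondimensionalization maps for a homogeneous isotropic medium.

    Parameters
    ----------
    rho:
        Logistic growth rate, units 1/time.  Must be positive.
    D:
        Scalar diffusivity, units length**2/time.  Must be positive.

    The dimensionless variables are ``t~ = rho t``, ``v~ = v / sqrt(rho D)``
    and the co-moving coordinate ``x~ = sqrt(rho / D) x - v~ t~``.
    """

    rho: float
    D: float

    def __post_init__(self) -> None:
        if not (self.rho > 0.0 and np.isfinite(self.rho)):
            raise ValueError(f"growth rate rho must be positive, got {self.rho}")
        if not (self.D > 0.0 and np.isfinite(self.D)):
            raise ValueError(f"diffusivity D must be positive, got {self.D}")

    def to_dimensionless(self, t, x, v):
        """Map dimensional ``(t, x, v)`` to ``(t~, x~, v~)``."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        v = np.asarray(v, dtype=float)
        t_t = self.rho * t
        v_t = v / np.sqrt(self.rho * self.D)
        x_t = np.sqrt(self.rho / self.D) * x - v_t * t_t
        return t_t, x_t, v_t

    def to_dimensional(self, t_tilde, x_tilde, v_tilde):
        """Inverse of :meth:`to_dimensionless`; restores ``(t, x, v)``."""
        t_tilde = np.asarray(t_tilde, dtype=float)
        x_tilde = np.asarray(x_tilde, dtype=float)
        v_tilde = np.asarray(v_tilde, dtype=float)
        t = t_tilde / self.rho
        v = v_tilde * np.sqrt(self.rho * self.D)
        x = (x_tilde + v_tilde * t_tilde) * np.sqrt(self.D / self.rho)
        return t, x, v


@dataclasses.dataclass(frozen=True)
class WaveParams:
    """Dimensionless penalty / wave speed ``v~ >= 0``.

    The analytically solvable profile corresponds to
    ``v_tilde == ANALYTIC_WAVE_SPEED == 5/sqrt(6)``.
    """

    v_tilde: float = ANALYTIC_WAVE_SPEED

    def __post_init__(self) -> None:
        if not (self.v_tilde >= 0.0 and np.isfinite(self.v_tilde)):
            raise ValueError(f"wave speed must be non-negative, got {self.v_tilde}")


def limit_profile(x_tilde):
    """Co-moving limit front ``U(x~) = (1 + exp(x~/sqrt(6)))**-2``.

    Strictly decreasing, with ``U -> 1`` for ``x~ -> -inf`` and ``U -> 0``
    for ``x~ -> +inf``.  Evaluated through ``logaddexp`` so large arguments
    neither overflow nor underflow prematurely.
    """
    s = np.asarray(x_tilde, dtype=float) / SQRT6
    return np.exp(-2.0 * np.logaddexp(0.0, s))


def limit_gradient(x_tilde):
    """Slope of the limit front, ``-sqrt(2/3) e^s / (1+e^s)**3`` with
    ``s = x~/sqrt(6)``.  Strictly negative, vanishing in both tails."""
    s = np.asarray(x_tilde, dtype=float) / SQRT6
    return -SQRT_2_3 * np.exp(s - 3.0 * np.logaddexp(0.0, s))


def limit_curvature(x_tilde):
    """Second derivative of the limit front.

    ``U''(x~) = (1/3) e^s (2 e^s - 1) / (1 + e^s)**4`` with ``s = x~/sqrt(6)``.
    """
    s = np.asarray(x_tilde, dtype=float) / SQRT6
    lse = np.logaddexp(0.0, s)
    return (2.0 * np.exp(2.0 * s - 4.0 * lse) - np.exp(s - 4.0 * lse)) / 3.0


def limit_inverse(U):
    """Position on the limit front at amplitude ``U``:
    ``x~(U) = sqrt(6) ln(1/sqrt(U) - 1)``.

    Only defined on the open interval ``0 < U < 1``; values outside are the
    unreachable plateaus of the front and raise ``ValueError``.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U <= 0.0) or np.any(U >= 1.0):
        raise ValueError("amplitude outside the invertible range (0, 1)")
    return SQRT6 * np.log(1.0 / np.sqrt(U) - 1.0)


def penalty(U, v_mag):
    """Stationalization penalty ``p(U) = |v| sqrt(2/3) (1 - sqrt(U)) U``.

    ``v_mag`` is the penalty magnitude (the assumed front speed).  The term
    vanishes at both logistic fixed points and is non-negative on [0, 1];
    it is exactly ``-v_mag * U'(x~(U))`` for amplitudes in (0, 1).

    Out-of-range amplitudes are a solver-level concern (see
    :func:`positivity_guard`) and are rejected here.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U < 0.0) or np.any(U > 1.0):
        raise ValueError("penalty requires amplitudes in [0, 1]")
    if not v_mag >= 0.0:
        raise ValueError(f"penalty magnitude must be non-negative, got {v_mag}")
    return v_mag * SQRT_2_3 * (1.0 - np.sqrt(U)) * U


def effective_reaction(u, rho, v_mag):
    """Net reaction ``rho u (1 - u) - p(u, v_mag)`` of the stationalized model.

    With ``rho = 1`` and ``v_mag = 5/sqrt(6)`` the term is *penalizing*
    (negative) for ``0 < u < 4/9`` and a growth term for ``4/9 < u < 1``;
    the imaging visibility threshold 0.16 lies inside the penalizing regime,
    which is what makes small-amplitude initial guesses select the outward
    moving branch.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("effective_reaction requires amplitudes in [0, 1]")
    return rho * u * (1.0 - u) - penalty(u, v_mag)


class GuardResult(NamedTuple):
    rate: np.ndarray | float
    active: np.ndarray | bool


def positivity_guard(omega, rho):
    """Surrogate reaction for amplitudes that left the physical range.

    Returns ``(rate, active)``: wherever ``omega < 0`` the rate is
    ``-rho omega`` and wherever ``omega > 1`` it is ``rho (1 - omega)``,
    both pushing the amplitude back toward [0, 1].  For in-range
    amplitudes the guard is inactive (``rate == 0``, ``active == False``)
    and the model's own reaction applies.
    """
    if not rho > 0.0:
        raise ValueError(f"growth rate must be positive, got {rho}")
    omega = np.asarray(omega, dtype=float)
    below = omega < 0.0
    above = omega > 1.0
    rate = np.where(below, -rho * omega, np.where(above, rho * (1.0 - omega), 0.0))
    active = below | above
    if rate.ndim == 0:
        return GuardResult(float(rate), bool(active))
    return GuardResult(rate, active)


def comoving_residual(x_tilde, v_tilde):
    """Residual of the stationary co-moving equation at the closed form.

    Evaluates ``U'' + U (1 - U) + v~ U'`` with exact derivatives.  The
    residual is identically zero (to round-off) precisely for
    ``v_tilde == 5/sqrt(6)``; for any other speed it is O(1) near the front.
    """
    U = limit_profile(x_tilde)
    return limit_curvature(x_tilde) + U * (1.0 - U) + v_tilde * limit_gradient(x_tilde)


def fit_wave_speed(x_tilde=None):
    """Wave speed that zeroes the co-moving residual, by least squares.

    The residual is linear in the speed, so the minimizer of
    ``||U'' + U(1-U) + v U'||`` over a sample of positions has the closed
    form ``v* = -<a, b> / <b, b>`` with ``a = U'' + U(1-U)`` and
    ``b = U'``.  Recovering ``5/sqrt(6)`` from this fit is a strong
    self-consistency check of all three closed-form derivatives.
    """
    if x_tilde is None:
        x_tilde = np.linspace(-20.0, 20.0, 4001)
    x_tilde = np.asarray(x_tilde, dtype=float)
    U = limit_profile(x_tilde)
    a = limit_curvature(x_tilde) + U * (1.0 - U)
    b = limit_gradient(x_tilde)
    return float(-np.dot(a, b) / np.dot(b, b))


def interior_reaction_root(rho=1.0, v_mag=ANALYTIC_WAVE_SPEED):
    """Interior zero of the effective reaction on (0, 1).

    Found by bracketing and Brent polishing; for ``rho = 1`` and the
    analytic speed the root is exactly 4/9 (in ``s = sqrt(u)`` the
    condition reads ``3 s**2 - 5 s + 2 = 0``).
    """
    from scipy.optimize import brentq

    def f(u):
        return float(effective_reaction(u, rho, v_mag))

    grid = np.linspace(1e-9, 1.0 - 1e-9, 2001)
    vals = effective_reaction(grid, rho, v_mag)
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise ValueError("effective reaction has no interior sign change")
    i = crossings[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
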