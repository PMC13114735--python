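"""Local (well-mixed) kinetics of the S/I/R rumor model.

The reaction part couples logistic growth of the susceptible pool with a
nonlinear incidence beta*S*I^2 (social reinforcement: adoption requires
repeated exposure, hence quadratic in spreader density):

    dS/dt = r S (1 - S/K) - beta S I^2 - mu1 S
    dI/dt = beta S I^2 - mu2 I - alpha I
    dR/dt = alpha I - mu3 R

Positive equilibria are the positive roots of the depressed cubic

    f(I) = K beta^2 I^3 + K beta (mu1 - r) I + r (mu2 + alpha),

with S* = (mu2+alpha)/(beta I*) and R* = alpha I*/mu3 back-substituted.
Two positive roots exist exactly when mu1 < r and f at the positive
critical point of f is negative; the smaller root is the "lower" branch,
the larger the "upper" branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "EquilibriumPoint",
    "CharPoly",
    "PRESET_PATTERN",
    "PRESET_INDONESIA2020",
    "reaction_rates",
    "equilibrium_cubic_coeffs",
    "solve_equilibria",
    "local_jacobian",
    "char_poly_coeffs",
]


class KineticsInputError(ValueError):
    """Invalid parameter set or inconsistent equilibrium/parameters pair."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and diffusion rates; every rate is strictly positive.

    r          natural growth rate of susceptibles (1/time)
    K          carrying capacity (density)
    beta       transmission rate of the nonlinear incidence (1/(density^2 time))
    mu1..mu3   replacement (turnover) rates of S, I, R (1/time)
    alpha      recovery rate of spreaders (1/time)
    d1..d3     diffusion coefficients of S, I, R on the network (1/time)
    """

    r: float
    K: float
    beta: float
    mu1: float
    mu2: float
    mu3: float
    alpha: float
    d1: float = 1.0
    d2: float = 1.0
    d3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "K", "beta", "mu1", "mu2", "mu3", "alpha"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise KineticsInputError(f"parameter {name} must be strictly positive, got {value}")
        for name in ("d1", "d2", "d3"):
            value = getattr(self, name)
            if not (value >= 0 and math.isfinite(value)):
                raise KineticsInputError(f"diffusion coefficient {name} must be non-negative, got {value}")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


#: Pattern-formation parameter set used throughout the network simulations
#: (r = 2.6 reading; the large d1/d2 ratio is what destabilizes the modes).
PRESET_PATTERN = ModelParams(
    r=2.6, K=0.5, beta=0.8, mu1=0.4, mu2=0.1, mu3=0.3, alpha=0.1,
    d1=10.0, d2=0.1, d3=0.1,
)

#: Calibrated kinetic rates for the 2020 Indonesian COVID-19 rumor wave
#: (demonstration preset; diffusion coefficients are placeholders since the
#: calibration is spatially homogeneous).
PRESET_INDONESIA2020 = ModelParams(
    r=4.2125, K=0.9938, beta=0.9996, mu1=0.0045, mu2=0.0654, mu3=0.5481,
    alpha=0.0369, d1=1.0, d2=1.0, d3=1.0,
)


@dataclass(frozen=True)
class EquilibriumPoint:
    """A positive steady state (S*, I*, R*) of the local kinetics.

    ``branch`` labels which positive cubic root this is ("lower" = smaller
    I*, "upper" = larger I*).  The cubic diagnostics carry the critical
    points I' < 0 < I'' of f and the value f(I''), which classifies the
    root count; ``degenerate`` marks the tangent (double-root) case.
    """

    S_star: float
    I_star: float
    R_star: float
    branch: str
    I_prime: float
    I_dblprime: float
    f_at_I_dblprime: float
    degenerate: bool = False


@dataclass(frozen=True)
class CharPoly:
    """Coefficients of lambda^3 + a1 lambda^2 + a2 lambda + a3."""

    a1: float
    a2: float
    a3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)


def reaction_rates(S, I, R, params: ModelParams):
    """Right-hand side of the local kinetics; accepts scalars or arrays."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    R = np.asarray(R, dtype=float)
    if (S < 0).any() or (I < 0).any() or (R < 0).any():
        raise KineticsInputError("densities must be non-negative")
    p = params
    dS = p.r * S * (1.0 - S / p.K) - p.beta * S * I**2 - p.mu1 * S
    dI = p.beta * S * I**2 - p.mu2 * I - p.alpha * I
    dR = p.alpha * I - p.mu3 * R
    if dS.ndim == 0:
        return float(dS), float(dI), float(dR)
    return dS, dI, dR


def equilibrium_cubic_coeffs(params: ModelParams) -> tuple[float, float, float]:
    """Coefficients (c3, c1, c0) of f(I) = c3 I^3 + c1 I + c0.

    c3 = K beta^2, c1 = K beta (mu1 - r), c0 = r (mu2 + alpha): eliminating
    S and R from the steady-state equations leaves this depressed cubic in
    I, so the quadratic coefficient vanishes identically and the three
    roots always sum to zero.  c1 < 0 iff mu1 < r, which is why mu1 >= r
    precludes positive roots (f is then increasing on I > 0 with f(0) > 0).
    """
    p = params
    return (p.K * p.beta**2, p.K * p.beta * (p.mu1 - p.r), p.r * (p.mu2 + p.alpha))


def _cubic_f(I: float, c3: float, c1: float, c0: float) -> float:
    return c3 * I**3 + c1 * I + c0


def solve_equilibria(params: ModelParams) -> list[EquilibriumPoint]:
    """All positive equilibria of the local kinetics, ordered lower then upper.

    Returns [] when mu1 >= r (f is non-decreasing on I > 0) or when f stays
    positive at its interior minimum; a tangency (double root) comes back as
    a single point flagged ``degenerate``.
    """
    p = params
    c3, c1, c0 = equilibrium_cubic_coeffs(p)
    if p.mu1 >= p.r:
        return []
    # critical points of f are +-sqrt(-c1/(3 c3)) = +-sqrt((r - mu1)/(3 beta))
    I_dbl = math.sqrt(-c1 / (3.0 * c3))
    f_min = _cubic_f(I_dbl, c3, c1, c0)
    diag = dict(I_prime=-I_dbl, I_dblprime=I_dbl, f_at_I_dblprime=f_min)

    def make(I_star: float, branch: str, degenerate: bool = False) -> EquilibriumPoint:
        # Newton polish on the companion-matrix root
        for _ in range(4):
            fp = 3.0 * c3 * I_star**2 + c1
            if fp == 0.0:
                break
            I_star -= _cubic_f(I_star, c3, c1, c0) / fp
        return EquilibriumPoint(
            S_star=(p.mu2 + p.alpha) / (p.beta * I_star),
            I_star=I_star,
            R_star=p.alpha * I_star / p.mu3,
            branch=branch,
            degenerate=degenerate,
            **diag,
        )

    if f_min > 0.0:
        return []
    if f_min == 0.0:
        return [make(I_dbl, "lower", degenerate=True)]
    roots = np.roots([c3, 0.0, c1, c0])
    pos = sorted(
        float(z.real)
        for z in roots
        if abs(z.imag) <= 1e-9 * max(1.0, abs(z.real)) and z.real > 0.0
    )
    return [make(I, branch) for I, branch in zip(pos, ("lower", "upper"))]


def _check_consistent(eq: EquilibriumPoint, params: ModelParams, tol: float = 1e-8) -> None:
    c3, c1, c0 = equilibrium_cubic_coeffs(params)
    scale = max(abs(c3) * eq.I_star**3, abs(c1) * eq.I_star, abs(c0), 1.0)
    if abs(_cubic_f(eq.I_star, c3, c1, c0)) > tol * scale:
        raise KineticsInputError("equilibrium point is not a root of the cubic for these parameters")


def local_jacobian(eq: EquilibriumPoint, params: ModelParams) -> np.ndarray:
    """3x3 Jacobian of the kinetics at a positive equilibrium.

    At equilibrium the (1,1) entry r - 2rS*/K - mu1 - beta I*^2 collapses to
    -rS*/K, and (1,2) = -2 beta S* I* = -2(mu2+alpha); the matrix below uses
    the explicit forms so the collapse is a checkable identity, not an input.
    """
    _check_consistent(eq, params)
    p = params
    S, I = eq.S_star, eq.I_star
    return np.array(
        [
            [p.r - 2.0 * p.r * S / p.K - p.mu1 - p.beta * I**2, -2.0 * (p.mu2 + p.alpha), 0.0],
            [p.beta * I**2, p.mu2 + p.alpha, 0.0],
            [0.0, p.alpha, -p.mu3],
        ]
    )


def char_poly_coeffs(eq: EquilibriumPoint, params: ModelParams) -> CharPoly:
    """Coefficients of the cubic characteristic polynomial at an equilibrium.

    lambda = -mu3 is always a root (the R row couples one-way), so the
    polynomial factors as (lambda + mu3)(lambda^2 + ...).
    """
    _check_consistent(eq, params)
    p = params
    rSK = p.r * eq.S_star / p.K
    ma = p.mu2 + p.alpha
    return CharPoly(
        a1=p.mu3 - p.mu2 - p.alpha + rSK,
        a2=ma * (2.0 * p.r - p.mu3 - 2.0 * p.mu1 - 3.0 * rSK) + p.mu3 * rSK,
        a3=p.mu3 * ma * (2.0 * p.r - 2.0 * p.mu1 - 3.0 * rSK),
    )
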