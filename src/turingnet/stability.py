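"""Linear stability and Turing-instability criteria on networks.

Linearizing the network system about a homogeneous positive equilibrium
gives a 3N x 3N Jacobian built from the per-compartment Laplacians A, B, C
and the local 3x3 Jacobian.  Three levels of analysis are provided:

* H1 — Hurwitz stability of the local kinetics (homogeneous perturbations).
* Homogeneous networks (A = B = C) — the perturbation decomposes along the
  Laplacian eigenbasis, giving per-mode quadratics lambda^2 + u(eta) lambda
  + v(eta); modes with v(eta) < 0 grow, and v < 0 exactly on an interval
  (eta1*, eta2*) of negative "wavenumbers".  Turing instability requires a
  network eigenvalue strictly inside that interval.
* Heterogeneous three-layer networks — A, B, C cannot be co-diagonalized,
  so only necessary conditions are available: a norm bound phi on the
  spectral radius of the full Jacobian yields mode-wise first-order
  inequalities (conditions H2 / H3) in the eigenvalues theta_m of A.

``full_jacobian_spectrum`` assembles the dense 3N x 3N Jacobian and is the
ground-truth oracle every criterion is checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kinetics import CharPoly, EquilibriumPoint, ModelParams, _check_consistent
from .networks import LayeredNetwork

__all__ = [
    "SpectrumSet",
    "H1Report",
    "TuringIntervalReport",
    "DispersionResult",
    "HeteroConditionReport",
    "h1_check",
    "routh_hurwitz_oracle",
    "dispersion_uv",
    "turing_interval",
    "homogeneous_turing_report",
    "phi_bound",
    "hetero_necessary_report",
    "full_jacobian_spectrum",
]


class StabilityInputError(ValueError):
    """Mismatched network/equilibrium inputs for a stability computation."""


@dataclass
class SpectrumSet:
    """Eigen-decompositions of the three layer Laplacians.

    Eigenvalues are real, non-positive, sorted descending (0 first);
    eigenvector columns are orthonormal.
    """

    theta: np.ndarray  # eigenvalues of A
    delta: np.ndarray  # eigenvalues of B
    eta: np.ndarray    # eigenvalues of C
    vectors_A: np.ndarray
    vectors_B: np.ndarray
    vectors_C: np.ndarray

    @classmethod
    def from_network(cls, net: LayeredNetwork) -> "SpectrumSet":
        out = []
        for L in (net.A, net.B, net.C):
            w, V = np.linalg.eigh(L)
            order = np.argsort(-w)  # descending: 0 first
            out.append((w[order], V[:, order]))
        (th, VA), (de, VB), (et, VC) = out
        return cls(th, de, et, VA, VB, VC)


def _eq_quantities(eq: EquilibriumPoint, params: ModelParams):
    p = params
    rSK = p.r * eq.S_star / p.K
    ma = p.mu2 + p.alpha
    j11 = p.r - 2.0 * rSK - p.mu1 - p.beta * eq.I_star**2  # equals -rS*/K at equilibrium
    return rSK, ma, j11


# ---------------------------------------------------------------------------
# H1 and the Routh–Hurwitz oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class H1Report:
    """Outcome of the two-inequality Hurwitz condition with its margins.

    ``ineq1`` = mu2 + alpha - rS*/K (must be < 0);
    ``ineq2`` = 2r - 3rS*/K - 2mu1 (must be > 0).
    """

    holds: bool
    ineq1: float
    ineq2: float
    ineq1_holds: bool
    ineq2_holds: bool


def h1_check(eq: EquilibriumPoint, params: ModelParams, eps: float = 0.0) -> H1Report:
    """Hurwitz-derived stability condition of the homogeneous equilibrium.

    Both inequalities are strict; ``eps`` widens the boundary exclusion for
    reporting near-marginal cases.
    """
    _check_consistent(eq, params)
    rSK, ma, _ = _eq_quantities(eq, params)
    ineq1 = ma - rSK
    ineq2 = 2.0 * params.r - 3.0 * rSK - 2.0 * params.mu1
    ok1, ok2 = ineq1 < -eps, ineq2 > eps
    return H1Report(ok1 and ok2, ineq1, ineq2, ok1, ok2)


def routh_hurwitz_oracle(cp: CharPoly) -> bool:
    """Full cubic Routh–Hurwitz test: a1 > 0, a3 > 0, a1 a2 - a3 > 0.

    Independent of h1_check; true iff every root of
    lambda^3 + a1 lambda^2 + a2 lambda + a3 has negative real part.
    """
    return cp.a1 > 0.0 and cp.a3 > 0.0 and cp.a1 * cp.a2 - cp.a3 > 0.0


# ---------------------------------------------------------------------------
# Homogeneous-network dispersion relation
# ---------------------------------------------------------------------------

def dispersion_uv(eq: EquilibriumPoint, params: ModelParams, eta) -> tuple:
    """Coefficients (u, v) of the per-mode quadratic lambda^2 + u lambda + v.

    ``eta`` is a non-positive Laplacian eigenvalue (scalar or array).  The
    raw forms (built from the explicit Jacobian entries) and the simplified
    forms (after the equilibrium identities) are both evaluated; they agree
    at any true equilibrium and the simplified values are returned.
    """
    eta = np.asarray(eta, dtype=float)
    if (eta > 0).any():
        raise StabilityInputError("Laplacian eigenvalues must be non-positive")
    _check_consistent(eq, params)
    p = params
    rSK, ma, j11 = _eq_quantities(eq, params)
    bI2 = p.beta * eq.I_star**2

    # raw: from the 2x2 mode matrix [[d1 eta + j11, -2 ma], [bI2, d2 eta + ma]]
    u_raw = -(p.d1 * eta + j11) - (p.d2 * eta + ma)
    v_raw = (p.d1 * eta + j11) * (p.d2 * eta + ma) + 2.0 * ma * bI2
    # simplified (j11 -> -rS*/K, bI2 -> r - rS*/K - mu1)
    u = -(p.d1 + p.d2) * eta + rSK - ma
    v = (
        p.d1 * p.d2 * eta**2
        + (p.d1 * ma - p.d2 * rSK) * eta
        + ma * (2.0 * p.r - 3.0 * rSK - 2.0 * p.mu1)
    )
    scale = max(1.0, float(np.max(np.abs(v))), float(np.max(np.abs(u))))
    if np.max(np.abs(u - u_raw)) > 1e-8 * scale or np.max(np.abs(v - v_raw)) > 1e-8 * scale:
        raise StabilityInputError("raw and simplified dispersion forms disagree; eq is not an equilibrium")
    if u.ndim == 0:
        return float(u), float(v)
    return u, v


@dataclass(frozen=True)
class TuringIntervalReport:
    """The four-inequality necessary condition and the unstable-mode interval.

    ``eta1_star <= eta2_star <= 0`` are the roots of the mode polynomial
    constant term g(eta) when all four inequalities hold; otherwise None.
    """

    holds: bool
    ineq_h1_first: float      # mu2 + alpha - rS*/K          (< 0 required)
    ineq_linear: float        # d1(mu2+alpha) - d2 rS*/K     (> 0 required)
    ineq_discriminant: float  # b^2 - 4ac of g               (> 0 required)
    ineq_h1_second: float     # 2r - 3rS*/K - 2mu1           (> 0 required)
    g_coeffs: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    eta1_star: float | None = None
    eta2_star: float | None = None

    @property
    def interval(self) -> tuple[float, float] | None:
        if self.eta1_star is None:
            return None
        return (self.eta1_star, self.eta2_star)


def turing_interval(eq: EquilibriumPoint, params: ModelParams) -> TuringIntervalReport:
    """Evaluate the homogeneous-network necessary condition for instability.

    g(eta) = d1 d2 eta^2 + (d1(mu2+alpha) - d2 rS*/K) eta
             + (mu2+alpha)(2r - 3rS*/K - 2mu1)
    must take negative values at some admissible eta < 0; that happens iff
    the four strict inequalities hold, and then g < 0 exactly on
    (eta1*, eta2*), an interval of negative reals.
    """
    _check_consistent(eq, params)
    p = params
    rSK, ma, _ = _eq_quantities(eq, params)
    a = p.d1 * p.d2
    b = p.d1 * ma - p.d2 * rSK
    c = ma * (2.0 * p.r - 3.0 * rSK - 2.0 * p.mu1)
    disc = b * b - 4.0 * a * c
    i1 = ma - rSK
    i4 = 2.0 * p.r - 3.0 * rSK - 2.0 * p.mu1
    holds = (i1 < 0.0) and (b > 0.0) and (disc > 0.0) and (i4 > 0.0)
    if not holds:
        return TuringIntervalReport(False, i1, b, disc, i4, (a, b, c))
    sq = math.sqrt(disc)
    eta1 = (-b - sq) / (2.0 * a)
    eta2 = (-b + sq) / (2.0 * a)
    return TuringIntervalReport(True, i1, b, disc, i4, (a, b, c), eta1, eta2)


@dataclass
class DispersionResult:
    """Mode-by-mode dispersion diagnostics on a homogeneous network."""

    branch: str
    eta: np.ndarray
    u_of_eta: np.ndarray
    v_of_eta: np.ndarray
    growth_rates: np.ndarray          # max Re lambda of each mode quadratic
    interval: TuringIntervalReport
    h1: H1Report
    unstable_modes: list[int]
    turing_capable: bool


def homogeneous_turing_report(
    net: LayeredNetwork, eq: EquilibriumPoint, params: ModelParams
) -> DispersionResult:
    """Combine the Turing interval with the actual network spectrum.

    The network is Turing-capable iff H1 holds (stable to homogeneous
    perturbations), the interval exists, and at least one Laplacian
    eigenvalue lies strictly inside it.
    """
    if not net.is_homogeneous:
        raise StabilityInputError(
            "homogeneous_turing_report requires A = B = C; use hetero_necessary_report"
        )
    eta = np.sort(np.linalg.eigvalsh(net.C))[::-1]
    eta = np.minimum(eta, 0.0)  # clamp eigensolver noise at the 0 eigenvalue
    u, v = dispersion_uv(eq, params, eta)
    disc = u**2 - 4.0 * v
    sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
    growth = np.where(disc >= 0.0, 0.5 * (-u + sqrt_disc), -0.5 * u)
    interval = turing_interval(eq, params)
    h1 = h1_check(eq, params)
    if interval.holds:
        unstable = [int(n) for n in np.nonzero(
            (eta > interval.eta1_star) & (eta < interval.eta2_star)
        )[0]]
    else:
        unstable = []
    return DispersionResult(
        branch=eq.branch,
        eta=eta,
        u_of_eta=np.atleast_1d(u),
        v_of_eta=np.atleast_1d(v),
        growth_rates=np.atleast_1d(growth),
        interval=interval,
        h1=h1,
        unstable_modes=unstable,
        turing_capable=h1.holds and interval.holds and len(unstable) > 0,
    )


# ---------------------------------------------------------------------------
# Heterogeneous networks: spectral bound phi and conditions H2/H3
# ---------------------------------------------------------------------------

def phi_bound(
    net: LayeredNetwork,
    eq: EquilibriumPoint,
    params: ModelParams,
    spectra: SpectrumSet | None = None,
    radical: bool = True,
) -> float:
    """Norm upper bound phi on the spectral radius of the full 3N x 3N Jacobian.

    phi = ||blockdiag|| + ||off-diagonal reaction block||, evaluated exactly:
    the diagonal blocks are symmetric, so their 2-norm is the max absolute
    eigenvalue max_n {|d1 theta_n + j11|, |d2 delta_n + mu2+alpha|,
    |mu3 - d3 eta_n|}; the constant off-diagonal block has 2-norm
    max{beta I*^2, sqrt(4(mu2+alpha)^2 + alpha^2)} (its Gram matrix is
    diagonal).  ``radical=False`` drops the square root on the second
    candidate, which breaks the bound and is kept only for comparison.
    """
    _check_consistent(eq, params)
    p = params
    _, ma, j11 = _eq_quantities(eq, params)
    sp = spectra or SpectrumSet.from_network(net)
    diag_norm = max(
        float(np.max(np.abs(p.d1 * sp.theta + j11))),
        float(np.max(np.abs(p.d2 * sp.delta + ma))),
        float(np.max(np.abs(p.mu3 - p.d3 * sp.eta))),
    )
    bI2 = p.beta * eq.I_star**2
    off = 4.0 * ma**2 + p.alpha**2
    off_norm = max(bI2, math.sqrt(off) if radical else off)
    return diag_norm + off_norm


@dataclass
class HeteroConditionReport:
    """Mode-itemized necessary conditions for heterogeneous-network instability.

    For every eigenvalue theta_m of the S-layer Laplacian A:
      q(theta_m)  = d1 theta_m + r - 2rS*/K - mu1 - beta I*^2  (= d1 theta_m - rS*/K)
      b1(theta_m) = -2(mu2+alpha)(d1 theta_m + r - 2rS*/K - mu1)
      b2(theta_m) = (mu2+alpha)(phi^2 - (d1 theta_m - rS*/K)
                                      (d1 theta_m + 2r - 3rS*/K - 2mu1))
    H2 needs the two base inequalities plus a mode with b1 > 0 (i.e.
    d1 theta_m + r - 2rS*/K - mu1 > 0); H3 covers the b1 < 0 branch, which
    then requires b2 > 0 at that mode.  ``H3_printed_reading`` evaluates the
    third inequality with the sign as printed (identical to H2's witness),
    kept for comparison with the derivation reading in ``H3_holds``.
    """

    phi: float
    phi_no_radical: float
    theta: np.ndarray
    q_of_theta: np.ndarray
    b1_of_theta: np.ndarray
    b2_of_theta: np.ndarray
    base_ineq1: float   # mu2 + alpha - rS*/K       (< 0)
    base_ineq2: float   # 2r - 3rS*/K - 2mu1        (> 0)
    base_holds: bool
    H2_holds: bool
    H2_witness: int | None
    H3_holds: bool
    H3_witness: int | None
    H3_printed_reading: bool
    necessary_met: bool = field(init=False)

    def __post_init__(self) -> None:
        self.necessary_met = self.H2_holds or self.H3_holds


def hetero_necessary_report(
    net: LayeredNetwork,
    eq: EquilibriumPoint,
    params: ModelParams,
    spectra: SpectrumSet | None = None,
) -> HeteroConditionReport:
    """Evaluate conditions H2 and H3 on a (possibly heterogeneous) network."""
    _check_consistent(eq, params)
    p = params
    rSK, ma, j11 = _eq_quantities(eq, params)
    sp = spectra or SpectrumSet.from_network(net)
    phi = phi_bound(net, eq, params, spectra=sp, radical=True)
    phi_nr = phi_bound(net, eq, params, spectra=sp, radical=False)
    theta = sp.theta
    q = p.d1 * theta + j11
    w = p.d1 * theta + p.r - 2.0 * rSK - p.mu1  # b1's bracket (= q + beta I*^2)
    b1 = -2.0 * ma * w
    b2 = ma * (phi**2 - (p.d1 * theta - rSK) * (p.d1 * theta + 2.0 * p.r - 3.0 * rSK - 2.0 * p.mu1))
    i1 = ma - rSK
    i2 = 2.0 * p.r - 3.0 * rSK - 2.0 * p.mu1
    base = (i1 < 0.0) and (i2 > 0.0)

    h2_modes = np.nonzero(w > 0.0)[0]
    h2 = base and h2_modes.size > 0
    h3_modes = np.nonzero((w < 0.0) & (b2 > 0.0))[0]
    h3 = base and h3_modes.size > 0
    # printed H3 block repeats w > 0 and adds b2 > 0
    h3_printed = base and bool(np.any((w > 0.0) & (b2 > 0.0)))

    return HeteroConditionReport(
        phi=phi,
        phi_no_radical=phi_nr,
        theta=theta,
        q_of_theta=q,
        b1_of_theta=b1,
        b2_of_theta=b2,
        base_ineq1=i1,
        base_ineq2=i2,
        base_holds=base,
        H2_holds=h2,
        H2_witness=int(h2_modes[0]) if h2 else None,
        H3_holds=h3,
        H3_witness=int(h3_modes[0]) if h3 else None,
        H3_printed_reading=h3_printed,
    )


# ---------------------------------------------------------------------------
# Dense full-Jacobian oracle
# ---------------------------------------------------------------------------

def full_jacobian(net: LayeredNetwork, eq: EquilibriumPoint, params: ModelParams) -> np.ndarray:
    """Assemble the dense 3N x 3N Jacobian of the network system at eq."""
    _check_consistent(eq, params)
    p = params
    _, ma, j11 = _eq_quantities(eq, params)
    N = net.n_nodes
    E = np.eye(N)
    Z = np.zeros((N, N))
    bI2 = p.beta * eq.I_star**2
    return np.block(
        [
            [p.d1 * net.A + j11 * E, -2.0 * ma * E, Z],
            [bI2 * E, p.d2 * net.B + ma * E, Z],
            [Z, p.alpha * E, p.d3 * net.C - p.mu3 * E],
        ]
    )


def full_jacobian_spectrum(
    net: LayeredNetwork,
    eq: EquilibriumPoint,
    params: ModelParams,
    max_nodes: int = 2000,
) -> np.ndarray:
    """All eigenvalues of the 3N x 3N Jacobian (dense, general solver).

    The matrix is non-symmetric, so eigenvalues may be complex.  Networks
    larger than ``max_nodes`` are refused — at that size a dense solve is
    no longer the right tool (use a sparse/iterative method instead).
    """
    if net.n_nodes > max_nodes:
        raise StabilityInputError(
            f"N={net.n_nodes} exceeds the dense-solve cap {max_nodes}; "
            "use a sparse or iterative eigensolver for networks this large"
        )
    return scipy.linalg.eigvals(full_jacobian(net, eq, params))
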