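"""Time integration of the network reaction–diffusion system.

Each compartment diffuses over its own layer Laplacian (A for S, B for I,
C for R; homogeneous networks use the same matrix three times) while the
local kinetics act node-wise:

    dS_i/dt = d1 (A S)_i + r S_i (1 - S_i/K) - beta S_i I_i^2 - mu1 S_i
    dI_i/dt = d2 (B I)_i + beta S_i I_i^2 - (mu2 + alpha) I_i
    dR_i/dt = d3 (C R)_i + alpha I_i - mu3 R_i

Integration is explicit forward Euler on sparse Laplacians.  The explicit
scheme can undershoot zero near sharp transients; values are clipped at 0
with a running count (interior steady states are unaffected).  Convergence
is judged on the max-norm of the right-hand side, so the steady-state
criterion does not depend on the step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .kinetics import EquilibriumPoint, ModelParams
from .networks import LayeredNetwork

__all__ = [
    "NodeState",
    "Trajectory",
    "PatternStats",
    "perturbed_equilibrium_init",
    "integrate",
    "rhs",
    "detect_steady",
    "pattern_stats",
]


class DynamicsInputError(ValueError):
    """Invalid initial state or integration setting."""


class DivergenceError(RuntimeError):
    """The explicit integration produced NaN/Inf."""


@dataclass
class NodeState:
    """Per-node densities S, I, R (vectors of equal length N)."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        n = self.S.shape[0]
        if self.I.shape != (n,) or self.R.shape != (n,):
            raise DynamicsInputError("S, I, R must be 1-d arrays of equal length")
        if not (np.isfinite(self.S).all() and np.isfinite(self.I).all() and np.isfinite(self.R).all()):
            raise DynamicsInputError("state contains non-finite values")
        if (self.S < 0).any() or (self.I < 0).any() or (self.R < 0).any():
            raise DynamicsInputError("densities must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]

    def copy(self) -> "NodeState":
        return NodeState(self.S.copy(), self.I.copy(), self.R.copy())


@dataclass
class Trajectory:
    """Stored snapshots of an integration run.

    ``times``/``states`` hold every ``stride``-th step plus the final one;
    ``converged`` reflects the residual (max-norm of the RHS) at the end,
    and ``clipped`` counts negative values zeroed by the positivity guard.
    """

    times: np.ndarray
    states: list[NodeState]
    dt: float
    converged: bool
    final_residual: float
    clipped: int = 0

    @property
    def final(self) -> NodeState:
        return self.states[-1]


@dataclass(frozen=True)
class PatternStats:
    """Node statistics of one compartment field at one instant."""

    mean: float
    sd: float
    min: float
    max: float
    heterogeneous: bool


def perturbed_equilibrium_init(
    eq: EquilibriumPoint, N: int, amplitude: float, seed: int
) -> NodeState:
    """Homogeneous equilibrium times node-wise (1 + U(-amplitude, amplitude)).

    amplitude must lie in [0, 1) so densities stay positive; seeded and
    reproducible.
    """
    if not 0.0 <= amplitude < 1.0:
        raise DynamicsInputError(f"amplitude must lie in [0, 1), got {amplitude}")
    rng = np.random.default_rng(seed)
    factors = 1.0 + rng.uniform(-amplitude, amplitude, size=(3, N))
    return NodeState(eq.S_star * factors[0], eq.I_star * factors[1], eq.R_star * factors[2])


def rhs(net: LayeredNetwork, params: ModelParams, state: NodeState,
        _sparse=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the network system at a state."""
    A, B, C = _sparse if _sparse is not None else (
        sp.csr_matrix(net.A), sp.csr_matrix(net.B), sp.csr_matrix(net.C))
    p = params
    S, I, R = state.S, state.I, state.R
    dS = p.d1 * (A @ S) + p.r * S * (1.0 - S / p.K) - p.beta * S * I**2 - p.mu1 * S
    dI = p.d2 * (B @ I) + p.beta * S * I**2 - (p.mu2 + p.alpha) * I
    dR = p.d3 * (C @ R) + p.alpha * I - p.mu3 * R
    return dS, dI, dR


def _stability_ceiling(net: LayeredNetwork, params: ModelParams) -> float:
    # crude explicit-Euler diffusion ceiling: dt * d * |lambda_min(L)| <= 2;
    # Gershgorin bounds |lambda_min| by 2 * max degree.
    bound = max(
        params.d1 * 2.0 * float(net.degrees_A.max(initial=0.0)),
        params.d2 * 2.0 * float(net.degrees_B.max(initial=0.0)),
        params.d3 * 2.0 * float(net.degrees_C.max(initial=0.0)),
    )
    return np.inf if bound == 0.0 else 2.0 / bound


def integrate(
    net: LayeredNetwork,
    params: ModelParams,
    init: NodeState,
    dt: float = 1e-3,
    t_end: float = 100.0,
    stride: int = 1000,
    residual_tol: float | None = None,
) -> Trajectory:
    """Forward-Euler integration of the layered network system.

    Snapshots are stored every ``stride`` steps (plus the final state).
    When ``residual_tol`` is given, integration stops early once the
    max-norm of the RHS drops below it.  Deterministic given ``init``.
    """
    if dt <= 0:
        raise DynamicsInputError("dt must be positive")
    if init.n_nodes != net.n_nodes:
        raise DynamicsInputError("state size does not match network size")
    ceiling = _stability_ceiling(net, params)
    if dt > ceiling:
        warnings.warn(
            f"dt={dt} exceeds the explicit-stability ceiling (~{ceiling:.3g}); "
            "expect oscillation or divergence",
            stacklevel=2,
        )
    A, B, C = sp.csr_matrix(net.A), sp.csr_matrix(net.B), sp.csr_matrix(net.C)
    sparse = (A, B, C)
    S, I, R = init.S.copy(), init.I.copy(), init.R.copy()
    n_steps = int(round(t_end / dt))
    times = [0.0]
    states = [NodeState(S.copy(), I.copy(), R.copy())]
    clipped = 0
    residual = np.inf

    state = NodeState(S, I, R)
    check_every = max(1, min(stride, 200))
    step = 0
    for step in range(1, n_steps + 1):
        dS, dI, dR = rhs(net, params, state, _sparse=sparse)
        S += dt * dS
        I += dt * dI
        R += dt * dR
        neg = (S < 0).sum() + (I < 0).sum() + (R < 0).sum()
        if neg:
            clipped += int(neg)
            np.maximum(S, 0.0, out=S)
            np.maximum(I, 0.0, out=I)
            np.maximum(R, 0.0, out=R)
        if not (np.isfinite(S).all() and np.isfinite(I).all() and np.isfinite(R).all()):
            raise DivergenceError(
                f"non-finite state at step {step} (t={step * dt:.4g}); try a smaller dt"
            )
        state = NodeState.__new__(NodeState)  # skip validation in the hot loop
        state.S, state.I, state.R = S, I, R
        if step % stride == 0:
            times.append(step * dt)
            states.append(NodeState(S.copy(), I.copy(), R.copy()))
        if residual_tol is not None and step % check_every == 0:
            dS, dI, dR = rhs(net, params, state, _sparse=sparse)
            residual = max(np.abs(dS).max(), np.abs(dI).max(), np.abs(dR).max())
            if residual < residual_tol:
                break

    dS, dI, dR = rhs(net, params, state, _sparse=sparse)
    residual = float(max(np.abs(dS).max(), np.abs(dI).max(), np.abs(dR).max()))
    # always store the final state
    final_t = step * dt if n_steps else 0.0
    if times[-1] != final_t:
        times.append(final_t)
        states.append(NodeState(S.copy(), I.copy(), R.copy()))
    tol = residual_tol if residual_tol is not None else 1e-7
    return Trajectory(
        times=np.asarray(times),
        states=states,
        dt=dt,
        converged=residual < tol,
        final_residual=residual,
        clipped=clipped,
    )


def detect_steady(traj: Trajectory, tol: float = 1e-7) -> tuple[bool, float]:
    """Steady iff the max-norm residual at the final stored state is < tol."""
    if not traj.states:
        raise DynamicsInputError("empty trajectory")
    return traj.final_residual < tol, traj.final_residual


def pattern_stats(field: np.ndarray, het_threshold: float = 1e-3) -> PatternStats:
    """Sample statistics of one node field; flags spatial heterogeneity.

    The flag is sd/|mean| > het_threshold (plain sd > threshold when the
    mean vanishes), a scale-free measure of departure from homogeneity.
    """
    field = np.asarray(field, dtype=float)
    mean = float(field.mean())
    sd = float(field.std())
    rel = sd / abs(mean) if mean != 0.0 else sd
    return PatternStats(mean=mean, sd=sd, min=float(field.min()),
                        max=float(field.max()), heterogeneous=rel > het_threshold)


def state_pattern_stats(state: NodeState, het_threshold: float = 1e-3) -> dict[str, PatternStats]:
    """PatternStats for each compartment of a state."""
    return {
        "S": pattern_stats(state.S, het_threshold),
        "I": pattern_stats(state.I, het_threshold),
        "R": pattern_stats(state.R, het_threshold),
    }
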