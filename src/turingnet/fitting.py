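"""Calibration of the cumulative-adoption model against a participation series.

The observable is the cumulative fraction N(t) of users who have spread
the rumor, which obeys dN/dt = beta S I^2 alongside the S/I/R kinetics.
With spatially flat initial data and zero-flux boundaries the diffusion
terms vanish identically, so calibration of a single aggregate series uses
the 4-ODE reduction:

    dS/dt = r S (1 - S/K) - beta S I^2 - mu1 S
    dI/dt = beta S I^2 - (mu2 + alpha) I
    dR/dt = alpha I - mu3 R
    dN/dt = beta S I^2        (non-decreasing by construction)

Fitting follows a greedy random-walk over the seven kinetic rates with a
least-squares objective on N(t): multiplicative log-normal proposals inside
box bounds, accepted only when the sum of squared errors decreases.  S, I,
R are latent; only N is scored.  The time integrator is classical
fixed-step RK4 (the forward model is smooth and non-stiff, and fourth-order
accuracy lets a coarse step serve the optimizer loop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import ModelParams, PRESET_INDONESIA2020

__all__ = [
    "ObservedSeries",
    "FitConfig",
    "FitResult",
    "DEFAULT_INIT",
    "DEFAULT_T_GRID",
    "DEFAULT_NOISE_SD",
    "forward_model",
    "synthetic_series",
    "score",
    "fit_random_walk_ls",
    "intervention_run",
    "load_series_csv",
    "save_series_csv",
]


class SeriesError(ValueError):
    """Malformed observed series or CSV input."""


#: Initial aggregate state (S0, I0, R0, N0) of the calibration runs.
DEFAULT_INIT: tuple[float, float, float, float] = (1.0, 0.1, 0.1, 0.002)

#: Daily grid spanning the 54-day observation window.
DEFAULT_T_GRID: np.ndarray = np.arange(1.0, 55.0)

#: Observation-noise scale used by the synthetic-series generator.
DEFAULT_NOISE_SD: float = 0.005

#: Kinetic-rate names subject to fitting (diffusion plays no role in the
#: aggregate reduction).
FIT_PARAM_NAMES: tuple[str, ...] = ("r", "K", "beta", "mu1", "mu2", "mu3", "alpha")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r": (1e-3, 10.0),
    "K": (1e-2, 2.0),
    "beta": (1e-3, 3.0),
    "mu1": (1e-4, 1.0),
    "mu2": (1e-4, 1.0),
    "mu3": (1e-3, 2.0),
    "alpha": (1e-4, 1.0),
}


@dataclass
class ObservedSeries:
    """Cumulative participation fraction sampled at strictly increasing times."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise SeriesError("times and values must be 1-d arrays of equal length")
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise SeriesError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FitConfig:
    """Random-walk fitting settings.

    ``initial_params`` seeds the walk; ``step_scale`` is the log-normal
    proposal sd per parameter per iteration (5% default).
    """

    initial_params: ModelParams
    initial_state: tuple[float, float, float, float] = DEFAULT_INIT
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    iterations: int = 3000
    step_scale: float = 0.05
    seed: int = 0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise SeriesError("iterations must be >= 0")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < math.inf):
                raise SeriesError(f"bounds for {name} must be finite, positive, ordered")


@dataclass
class FitResult:
    """Best parameters found, their scores, and the best-so-far SSE trace."""

    params: ModelParams
    rmse: float
    mape: float
    sse_trace: np.ndarray
    converged: bool
    accepted: int = 0


def _rhs(S: float, I: float, R: float, p: ModelParams):
    inc = p.beta * S * I * I
    return (
        p.r * S * (1.0 - S / p.K) - inc - p.mu1 * S,
        inc - (p.mu2 + p.alpha) * I,
        p.alpha * I - p.mu3 * R,
        inc,
    )


def forward_model(
    params: ModelParams,
    init: tuple[float, float, float, float] = DEFAULT_INIT,
    dt: float = 0.01,
    t_grid: np.ndarray = None,
) -> np.ndarray:
    """Integrate the aggregate model from t=0; returns rows (S, I, R, N) at t_grid.

    Fixed-step RK4; the step is shortened on the last sub-interval so each
    grid time is hit exactly.  N is non-decreasing because its rate
    beta S I^2 is non-negative.
    """
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    t_grid = np.asarray(t_grid, dtype=float)
    if dt <= 0:
        raise SeriesError("dt must be positive")
    if t_grid.size and ((np.diff(t_grid) <= 0).any() or t_grid[0] < 0):
        raise SeriesError("t_grid must be strictly increasing and non-negative")
    S, I, R, N = (float(x) for x in init)
    if min(S, I, R, N) < 0:
        raise SeriesError("initial state must be non-negative")
    out = np.empty((4, t_grid.size))
    t = 0.0
    for j, t_next in enumerate(t_grid):
        while t < t_next - 1e-12:
            h = min(dt, t_next - t)
            k1 = _rhs(S, I, R, params)
            k2 = _rhs(S + 0.5 * h * k1[0], I + 0.5 * h * k1[1], R + 0.5 * h * k1[2], params)
            k3 = _rhs(S + 0.5 * h * k2[0], I + 0.5 * h * k2[1], R + 0.5 * h * k2[2], params)
            k4 = _rhs(S + h * k3[0], I + h * k3[1], R + h * k3[2], params)
            S += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            I += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            R += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            N += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            t += h
            if not all(map(math.isfinite, (S, I, R, N))):
                raise SeriesError(f"forward model diverged near t={t:.4g}; try a smaller dt")
        out[:, j] = (S, I, R, N)
    return out


def synthetic_series(
    params: ModelParams,
    init: tuple[float, float, float, float] = DEFAULT_INIT,
    t_grid: np.ndarray = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    dt: float = 0.01,
) -> ObservedSeries:
    """Noisy cumulative-adoption curve: model N(t) plus i.i.d. Gaussian noise.

    Emulates a pre-aggregated daily participation series over the study
    window; values are clipped at 0 (a raw series may still jitter
    downward, which downstream code tolerates).
    """
    if noise_sd < 0:
        raise SeriesError("noise_sd must be >= 0")
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    t_grid = np.asarray(t_grid, dtype=float)
    N = forward_model(params, init, dt=dt, t_grid=t_grid)[3]
    rng = np.random.default_rng(seed)
    noisy = np.maximum(N + rng.normal(0.0, noise_sd, size=N.shape) if noise_sd else N, 0.0)
    return ObservedSeries(t_grid, noisy)


def score(series: ObservedSeries, model_values: np.ndarray) -> tuple[float, float]:
    """(RMSE, MAPE%) of model values against an observed series.

    MAPE excludes zero observations (their relative error is undefined);
    an all-zero series has no defined MAPE and raises.
    """
    pred = np.asarray(model_values, dtype=float)
    obs = series.values
    if pred.shape != obs.shape:
        raise SeriesError("model values and series must have equal length")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    nonzero = obs != 0.0
    if not nonzero.any():
        raise SeriesError("MAPE undefined: every observation is zero")
    mape = float(np.mean(np.abs((obs[nonzero] - pred[nonzero]) / obs[nonzero])) * 100.0)
    return rmse, mape


def fit_random_walk_ls(series: ObservedSeries, cfg: FitConfig) -> FitResult:
    """Greedy random-walk least-squares fit of the seven kinetic rates.

    Each iteration perturbs every rate multiplicatively
    (p -> p * exp(step_scale * z), z ~ N(0,1)), clips into the box bounds,
    and accepts iff the SSE of the modelled N(t) against the series
    decreases.  The best-so-far SSE trace is therefore non-increasing.
    Deterministic under ``cfg.seed``.
    """
    if len(series) == 0:
        raise SeriesError("cannot fit an empty series")
    rng = np.random.default_rng(cfg.seed)
    names = FIT_PARAM_NAMES
    lo = np.array([cfg.bounds[n][0] for n in names])
    hi = np.array([cfg.bounds[n][1] for n in names])
    current = np.clip([getattr(cfg.initial_params, n) for n in names], lo, hi)

    def sse(vec: np.ndarray) -> float:
        p = cfg.initial_params.with_(**dict(zip(names, map(float, vec))))
        N = forward_model(p, cfg.initial_state, dt=cfg.dt, t_grid=series.times)[3]
        return float(np.sum((series.values - N) ** 2))

    best = current
    best_sse = sse(current)
    trace = [best_sse]
    accepted = 0
    for _ in range(cfg.iterations):
        proposal = np.clip(best * np.exp(cfg.step_scale * rng.standard_normal(len(names))), lo, hi)
        s = sse(proposal)
        if s < best_sse:
            best, best_sse = proposal, s
            accepted += 1
        trace.append(best_sse)

    best_params = cfg.initial_params.with_(**dict(zip(names, map(float, best))))
    N_best = forward_model(best_params, cfg.initial_state, dt=cfg.dt, t_grid=series.times)[3]
    rmse, mape = score(series, N_best)
    return FitResult(
        params=best_params,
        rmse=rmse,
        mape=mape,
        sse_trace=np.asarray(trace),
        converged=accepted > 0 or cfg.iterations == 0,
        accepted=accepted,
    )


def intervention_run(
    params: ModelParams,
    init: tuple[float, float, float, float] = DEFAULT_INIT,
    t_grid: np.ndarray = None,
    t_switch: float = 30.0,
    alpha_new: float | None = None,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline vs boosted-recovery trajectories (rows S, I, R, N each).

    The intervened run switches alpha -> alpha_new at t_switch (debunking
    campaign); a switch after the grid end leaves it identical to baseline.
    """
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    t_grid = np.asarray(t_grid, dtype=float)
    if alpha_new is None or alpha_new <= 0:
        raise SeriesError("alpha_new must be positive")
    baseline = forward_model(params, init, dt=dt, t_grid=t_grid)
    if t_switch >= t_grid[-1]:
        return baseline, baseline.copy()
    pre_mask = t_grid <= t_switch
    pre_grid = np.concatenate([t_grid[pre_mask], [t_switch]]) if not (
        pre_mask.any() and t_grid[pre_mask][-1] == t_switch
    ) else t_grid[pre_mask]
    pre = forward_model(params, init, dt=dt, t_grid=pre_grid)
    switch_state = tuple(pre[:, -1])
    post_grid = t_grid[~pre_mask] - t_switch
    post = forward_model(params.with_(alpha=alpha_new), switch_state, dt=dt, t_grid=post_grid)
    n_pre = int(pre_mask.sum())
    intervened = np.empty_like(baseline)
    intervened[:, :n_pre] = pre[:, :n_pre]
    intervened[:, n_pre:] = post
    return baseline, intervened


def load_series_csv(path) -> ObservedSeries:
    """Read a two-column (time, value) CSV; a single header row is skipped."""
    times, values, rows = [], [], []
    with open(path) as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise SeriesError(f"row {rowno}: expected 2 columns, got {len(parts)}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if rowno == 1:
                    continue  # header
                raise SeriesError(f"row {rowno}: non-numeric cell")
            times.append(t)
            values.append(v)
            rows.append(rowno)
    if times:
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            raise SeriesError(f"row {rows[int(bad[0]) + 1]}: times not strictly increasing")
    return ObservedSeries(np.asarray(times), np.asarray(values))


def save_series_csv(series: ObservedSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("time,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.10g},{v:.10g}\n")
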