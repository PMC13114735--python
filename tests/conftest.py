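"""Shared fixtures: the pattern-formation parameter set, its equilibria, and
the (expensive, session-scoped) Turing-pattern and decay simulations on the
32x32 periodic quadrilateral-lattice torus."""

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

import turingnet as tn


@pytest.fixture(scope="session")
def pattern_params() -> tn.ModelParams:
    return tn.PRESET_PATTERN


@pytest.fixture(scope="session")
def equilibria_pattern(pattern_params):
    eqs = tn.solve_equilibria(pattern_params)
    assert [e.branch for e in eqs] == ["lower", "upper"]
    return eqs


@pytest.fixture(scope="session")
def upper_eq(equilibria_pattern):
    return equilibria_pattern[1]


@pytest.fixture(scope="session")
def lower_eq(equilibria_pattern):
    return equilibria_pattern[0]


@pytest.fixture(scope="session")
def torus32(pattern_params):
    return tn.build_lattice(32, 32, degree=4, boundary="periodic")


@dataclass
class SimRun:
    net: "tn.LayeredNetwork"
    params: "tn.ModelParams"
    eq: "tn.EquilibriumPoint"
    init: "tn.NodeState"
    init_sd_I: float
    traj: "tn.Trajectory"


@pytest.fixture(scope="session")
def turing_run(torus32, pattern_params, upper_eq) -> SimRun:
    """32x32 torus, 1%-perturbed upper equilibrium, run to residual < 1e-7.

    The strong S-layer diffusion (d1/d2 = 100) destabilizes an interval of
    lattice modes and the perturbation saturates into a stationary pattern.
    """
    init = tn.perturbed_equilibrium_init(upper_eq, torus32.n_nodes, 0.01, seed=1)
    traj = tn.integrate(
        torus32, pattern_params, init, dt=0.02, t_end=100000,
        stride=10**9, residual_tol=1e-7,
    )
    return SimRun(torus32, pattern_params, upper_eq, init, float(init.I.std()), traj)


@pytest.fixture(scope="session")
def decay_run(torus32, pattern_params, upper_eq) -> SimRun:
    """Same perturbation under equal diffusion d1=d2=d3=0.1: no unstable
    modes, so the perturbation must relax back to the homogeneous state."""
    params = pattern_params.with_(d1=0.1)
    init = tn.perturbed_equilibrium_init(upper_eq, torus32.n_nodes, 0.01, seed=1)
    traj = tn.integrate(
        torus32, params, init, dt=0.02, t_end=400, stride=10**9, residual_tol=1e-12,
    )
    return SimRun(torus32, params, upper_eq, init, float(init.I.std()), traj)
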