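"""H1/Hurwitz criteria, dispersion relation, Turing interval, phi bound, H2/H3,
and the dense full-Jacobian oracle."""

import math

import networkx as nx
import numpy as np
import pytest

import turingnet as tn
from turingnet.kinetics import CharPoly
from turingnet.networks import AdjacencySpec, assign_edge_permissions, decompose_layers
from turingnet.stability import StabilityInputError, full_jacobian

from test_kinetics import random_params


def random_connected_net(rng, n_max=20):
    n = int(rng.integers(4, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
        if nx.is_connected(g):
            return tn.LayeredNetwork.homogeneous(AdjacencySpec.from_graph(g))


def random_hetero_net(rng, n_max=30):
    n = int(rng.integers(5, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
        if nx.is_connected(g):
            break
    adj = AdjacencySpec.from_graph(g)
    perms = assign_edge_permissions(adj, "uniform7", seed=int(rng.integers(1 << 30)))
    return decompose_layers(adj, perms)


class TestH1:
    def test_upper_branch_stable_lower_not(self, pattern_params, upper_eq, lower_eq):
        up = tn.h1_check(upper_eq, pattern_params)
        assert up.holds and up.ineq1 < 0 and up.ineq2 > 0
        low = tn.h1_check(lower_eq, pattern_params)
        assert not low.holds and not low.ineq2_holds

    def test_margins_at_pattern_set(self, pattern_params, upper_eq):
        # frozen from direct evaluation of the two inequalities at the
        # corrected-cubic upper root (S* ~ 0.21493)
        rep = tn.h1_check(upper_eq, pattern_params)
        assert rep.ineq1 == pytest.approx(-0.9176428844920692, abs=1e-9)
        assert rep.ineq2 == pytest.approx(1.0470713465237924, abs=1e-9)

    def test_boundary_is_strict(self, pattern_params, upper_eq):
        rep = tn.h1_check(upper_eq, pattern_params, eps=10.0)
        assert not rep.holds


class TestRouthHurwitz:
    def test_known_cubics(self):
        assert tn.routh_hurwitz_oracle(CharPoly(3, 3, 1))      # (x+1)^3
        assert not tn.routh_hurwitz_oracle(CharPoly(-1, 1, 1))

    def test_agrees_with_eigenvalues_on_random_cubics(self):
        rng = np.random.default_rng(17)
        coeffs = rng.uniform(-3, 3, size=(10_000, 3))
        for a1, a2, a3 in coeffs:
            roots = np.roots([1.0, a1, a2, a3])
            stable = bool((roots.real < 0).all())
            # skip draws within eigensolver distance of the imaginary axis
            if np.abs(roots.real).min() < 1e-9:
                continue
            assert tn.routh_hurwitz_oracle(CharPoly(a1, a2, a3)) == stable

    def test_h1_equivalence_with_full_criterion_surveyed(self):
        """At true equilibria of random draws, H1 and the full Routh-Hurwitz
        test are compared; disagreements are surfaced, not hidden."""
        rng = np.random.default_rng(23)
        disagreements = []
        for _ in range(300):
            p = random_params(rng, with_two_roots=True)
            for eq in tn.solve_equilibria(p):
                h1 = tn.h1_check(eq, p).holds
                rh = tn.routh_hurwitz_oracle(tn.char_poly_coeffs(eq, p))
                if h1 != rh:
                    disagreements.append((p, eq.branch, h1, rh))
        # H1 => Routh-Hurwitz must always hold (sufficiency direction)
        assert not [d for d in disagreements if d[2] and not d[3]]


class TestDispersion:
    def test_u_v_at_zero_mode(self, pattern_params, upper_eq):
        p = pattern_params
        rSK = p.r * upper_eq.S_star / p.K
        u, v = tn.dispersion_uv(upper_eq, p, 0.0)
        assert u == pytest.approx(rSK - (p.mu2 + p.alpha), abs=1e-10)
        assert v == pytest.approx(
            (p.mu2 + p.alpha) * (2 * p.r - 3 * rSK - 2 * p.mu1), abs=1e-10
        )
        assert v > 0  # H1 holds at the upper branch

    def test_positive_eta_rejected(self, pattern_params, upper_eq):
        with pytest.raises(StabilityInputError):
            tn.dispersion_uv(upper_eq, pattern_params, 0.5)

    def test_interval_at_pattern_set(self, pattern_params, upper_eq):
        rep = tn.turing_interval(upper_eq, pattern_params)
        assert rep.holds
        a, b, c = rep.g_coeffs
        assert (a, b, c) == pytest.approx((1.0, 1.888235711550793, 0.20941426930475848), abs=1e-9)
        # independent quadratic-formula oracle
        disc = math.sqrt(b * b - 4 * a * c)
        assert rep.eta1_star == pytest.approx((-b - disc) / (2 * a), abs=1e-12)
        assert rep.eta2_star == pytest.approx((-b + disc) / (2 * a), abs=1e-12)
        assert rep.eta1_star < rep.eta2_star < 0
        # g vanishes at both roots
        for eta in (rep.eta1_star, rep.eta2_star):
            assert abs(a * eta**2 + b * eta + c) < 1e-9

    def test_equal_diffusion_closes_interval(self, pattern_params, upper_eq):
        rep = tn.turing_interval(upper_eq, pattern_params.with_(d1=0.1))
        assert not rep.holds and rep.ineq_linear <= 0 and rep.interval is None


class TestHomogeneousReport:
    def test_torus_has_unstable_modes(self, torus32, pattern_params, upper_eq):
        rep = tn.homogeneous_turing_report(torus32, upper_eq, pattern_params)
        assert rep.turing_capable and len(rep.unstable_modes) > 0
        lo, hi = rep.interval.interval
        for n in rep.unstable_modes:
            assert lo < rep.eta[n] < hi
            assert rep.v_of_eta[n] < 0
            assert rep.growth_rates[n] > 0

    def test_triangle_misses_interval(self, pattern_params, upper_eq):
        adj = AdjacencySpec(3, {(0, 1), (1, 2), (0, 2)})
        net = tn.LayeredNetwork.homogeneous(adj)  # eigenvalues {0, -3, -3}
        rep = tn.homogeneous_turing_report(net, upper_eq, pattern_params)
        assert rep.interval.holds and rep.unstable_modes == [] and not rep.turing_capable

    def test_single_node_never_capable(self, pattern_params, upper_eq):
        net = tn.LayeredNetwork(1, np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)))
        rep = tn.homogeneous_turing_report(net, upper_eq, pattern_params)
        assert not rep.turing_capable

    def test_heterogeneous_input_rejected(self, pattern_params, upper_eq):
        rng = np.random.default_rng(0)
        net = random_hetero_net(rng)
        with pytest.raises(StabilityInputError):
            tn.homogeneous_turing_report(net, upper_eq, pattern_params)


class TestPhiBound:
    def test_isolated_node_closed_form(self, pattern_params, upper_eq):
        p = pattern_params
        net = tn.LayeredNetwork(1, np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)))
        phi = tn.phi_bound(net, upper_eq, p)
        ma = p.mu2 + p.alpha
        j11 = -p.r * upper_eq.S_star / p.K
        bI2 = p.beta * upper_eq.I_star**2
        expected = max(abs(j11), ma, p.mu3) + max(bI2, math.sqrt(4 * ma**2 + p.alpha**2))
        assert phi == pytest.approx(expected, abs=1e-12)

    def test_offdiagonal_block_norm_vs_svd(self, pattern_params, upper_eq):
        p = pattern_params
        ma = p.mu2 + p.alpha
        bI2 = p.beta * upper_eq.I_star**2
        M = np.array([[0.0, -2 * ma, 0.0], [bI2, 0.0, 0.0], [0.0, p.alpha, 0.0]])
        svd_norm = np.linalg.svd(M, compute_uv=False)[0]
        assert svd_norm == pytest.approx(max(bI2, math.sqrt(4 * ma**2 + p.alpha**2)), abs=1e-12)

    def test_bounds_spectral_radius_on_random_heterogeneous_nets(self, pattern_params, upper_eq):
        rng = np.random.default_rng(31)
        for _ in range(25):
            net = random_hetero_net(rng, n_max=25)
            phi = tn.phi_bound(net, upper_eq, pattern_params)
            rho = np.max(np.abs(tn.full_jacobian_spectrum(net, upper_eq, pattern_params)))
            assert phi >= rho - 1e-9


class TestHeteroConditions:
    def test_zero_mode_q_identity(self, pattern_params, upper_eq, torus32):
        rep = tn.hetero_necessary_report(torus32, upper_eq, pattern_params)
        # theta sorted descending: index 0 is the zero mode, where
        # q = r - 2rS*/K - mu1 - beta I*^2 = -rS*/K < 0
        assert rep.theta[0] == pytest.approx(0.0, abs=1e-9)
        assert rep.q_of_theta[0] == pytest.approx(
            -pattern_params.r * upper_eq.S_star / pattern_params.K, abs=1e-9
        )
        assert rep.q_of_theta[0] < 0

    def test_base_inequalities_match_homogeneous_report(self, pattern_params, upper_eq, torus32):
        het = tn.hetero_necessary_report(torus32, upper_eq, pattern_params)
        hom = tn.homogeneous_turing_report(torus32, upper_eq, pattern_params)
        assert het.base_ineq1 == pytest.approx(hom.interval.ineq_h1_first, abs=1e-12)
        assert het.base_ineq2 == pytest.approx(hom.interval.ineq_h1_second, abs=1e-12)

    def test_b1_b2_formulas(self, pattern_params, upper_eq, torus32):
        p = pattern_params
        rep = tn.hetero_necessary_report(torus32, upper_eq, pattern_params)
        rSK = p.r * upper_eq.S_star / p.K
        ma = p.mu2 + p.alpha
        m = 7
        th = rep.theta[m]
        assert rep.b1_of_theta[m] == pytest.approx(
            -2 * ma * (p.d1 * th + p.r - 2 * rSK - p.mu1), rel=1e-12
        )
        assert rep.b2_of_theta[m] == pytest.approx(
            ma * (rep.phi**2 - (p.d1 * th - rSK) * (p.d1 * th + 2 * p.r - 3 * rSK - 2 * p.mu1)),
            rel=1e-12,
        )

    def test_radical_reading_remains_a_bound_where_readings_differ(self):
        """Where the two off-diagonal-norm readings disagree, the radical one
        must still dominate the true spectral radius."""
        rng = np.random.default_rng(41)
        differed = 0
        for _ in range(100):
            p = random_params(rng, with_two_roots=True)
            eq = tn.solve_equilibria(p)[1]
            net = random_hetero_net(rng, n_max=12)
            rep = tn.hetero_necessary_report(net, eq, p)
            if abs(rep.phi - rep.phi_no_radical) > 1e-12:
                differed += 1
                rho = np.max(np.abs(tn.full_jacobian_spectrum(net, eq, p)))
                assert rep.phi >= rho - 1e-9
        assert differed > 0


class TestFullJacobianOracle:
    def test_single_node_matches_local_jacobian(self, pattern_params, upper_eq):
        net = tn.LayeredNetwork(1, np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)))
        lam = np.sort_complex(tn.full_jacobian_spectrum(net, upper_eq, pattern_params))
        local = np.sort_complex(np.linalg.eigvals(tn.local_jacobian(upper_eq, pattern_params)))
        assert np.allclose(lam, local, atol=1e-10)

    def test_zero_diffusion_gives_n_copies(self, pattern_params, upper_eq):
        p = pattern_params.with_(d1=0.0, d2=0.0, d3=0.0)
        adj = AdjacencySpec(4, {(0, 1), (1, 2), (2, 3)})
        net = tn.LayeredNetwork.homogeneous(adj)
        lam = np.sort_complex(tn.full_jacobian_spectrum(net, upper_eq, p))
        local = np.linalg.eigvals(tn.local_jacobian(upper_eq, p))
        expected = np.sort_complex(np.tile(local, 4))
        assert np.allclose(lam, expected, atol=1e-9)

    def test_block_reduction_identity_small(self, pattern_params, upper_eq):
        """Homogeneous 3N spectrum == union over modes of {d3 eta - mu3} and
        the dispersion-quadratic roots."""
        rng = np.random.default_rng(5)
        net = random_connected_net(rng, n_max=12)
        p = pattern_params
        lam = tn.full_jacobian_spectrum(net, upper_eq, p)
        eta = np.linalg.eigvalsh(net.C)
        expected = []
        for e in np.minimum(eta, 0.0):
            expected.append(p.d3 * e - p.mu3)
            u, v = tn.dispersion_uv(upper_eq, p, e)
            expected.extend(np.roots([1.0, u, v]))
        key = lambda z: (round(z.real, 6), round(z.imag, 6))
        got = sorted(lam, key=key)
        exp = sorted(np.asarray(expected, dtype=complex), key=key)
        assert np.allclose(got, exp, atol=1e-8)

    def test_r_layer_modes_always_decaying(self, pattern_params, upper_eq):
        # lambda = d3 eta_n - mu3 < 0 for every mode
        rng = np.random.default_rng(11)
        net = random_hetero_net(rng)
        eta = np.linalg.eigvalsh(net.C)
        assert (pattern_params.d3 * eta - pattern_params.mu3 < 0).all()

    def test_size_cap(self, pattern_params, upper_eq):
        net = tn.LayeredNetwork(3, np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(StabilityInputError, match="sparse"):
            tn.full_jacobian_spectrum(net, upper_eq, pattern_params, max_nodes=2)
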