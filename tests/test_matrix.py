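from collections import defaultdict
from fractions import Fraction

import numpy as np
import pytest

from dtrips import (
    CableParameters,
    build_q,
    class_lengths,
    discretise,
    greens_series,
    make_binary_tree,
    make_random_binary_tree,
    make_y_tree,
    matrix_greens,
    matrix_greens_all,
    relative_error,
    time_grid,
    trip_coefficient,
    trip_length,
)
from dtrips.enumeration import brute_force_walks
from dtrips.matrix_method import _orient_start_goal
from dtrips.morphology import InvalidParameterError

Y_ORDER = [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"), ("B", "D"), ("D", "B")]

Y_PRINTED = np.array([
    [0, 1, 0, 0, 0, 0],
    [-1 / 3, 0, 0, 2 / 3, 0, 2 / 3],
    [2 / 3, 0, 0, -1 / 3, 0, 2 / 3],
    [0, 0, 1, 0, 0, 0],
    [2 / 3, 0, 0, 2 / 3, 0, -1 / 3],
    [0, 0, 0, 0, 1, 0],
])


@pytest.fixture(scope="module")
def y_dtree():
    m = make_y_tree(100.0, 1.0, CableParameters())
    return discretise(m, m.el("AB"))


class TestDiscretise:
    def test_y_tree_edge_count(self, y_dtree):
        assert len(y_dtree.edges) == 6
        assert y_dtree.max_distortion == 0.0

    def test_edges_per_branch(self):
        m = make_y_tree(100.0, 1.0, CableParameters())
        dt = discretise(m, m.el("AB") / 20.0)
        assert all(n == 20 for n in dt.n_per_branch.values())
        assert len(dt.edges) == 2 * 3 * 20

    def test_reverse_edges_present(self, y_dtree):
        for e in y_dtree.edges:
            assert (e[1], e[0]) in y_dtree.index

    def test_coarse_dx_warns(self):
        m = make_y_tree(100.0, 1.0, CableParameters())
        with pytest.warns(UserWarning, match="distorted"):
            discretise(m, 3.0 * m.el("AB"))


class TestQ:
    def test_reproduces_printed_matrix(self, y_dtree):
        cm = build_q(y_dtree, edge_order=Y_ORDER, exact=True)
        assert np.allclose(cm.Q.toarray(), Y_PRINTED)

    def test_row_and_column_sums_exactly_one(self, y_dtree):
        cm = build_q(y_dtree, edge_order=Y_ORDER, exact=True)
        for i in range(6):
            assert sum(cm.exact[i, :]) == Fraction(1)
            assert sum(cm.exact[:, i]) == Fraction(1)

    def test_open_terminal_flips_sign(self):
        m = make_y_tree(100.0, 1.0, CableParameters(boundary="open"))
        dt = discretise(m, m.el("AB"))
        cm = build_q(dt, edge_order=Y_ORDER)
        Q = cm.Q.toarray()
        expected = Y_PRINTED.copy()
        expected[0, 1] = -1   # (B,A) -> (A,B) reflection at open terminal A
        expected[3, 2] = -1
        expected[5, 4] = -1
        assert np.allclose(Q, expected)

    def test_first_product(self, y_dtree):
        cm = build_q(y_dtree, edge_order=Y_ORDER)
        c1s = np.zeros(6)
        c1s[0] = 1.0
        assert np.allclose(cm.Q @ c1s, [0, -1 / 3, 2 / 3, 0, 2 / 3, 0])

    def test_coefficient_conservation(self, y_dtree):
        """Closed terminals, uniform radii: sum of c_k stays exactly 1."""
        cm = build_q(y_dtree)
        c = np.zeros(6)
        c[0] = 1.0
        for _ in range(50):
            c = cm.Q @ c
            assert c.sum() == pytest.approx(1.0, abs=1e-12)


class TestClassLengths:
    def test_frozen_values(self):
        """k edges minus the untravelled stubs; validated by enumeration."""
        L1, L2, L3, L4 = class_lengths(3, 0.25, 0.5, 2.0)
        assert L1 == pytest.approx(2.0 * (3 - 2 + 0.25 + 0.5))
        assert L2 == pytest.approx(2.0 * (3 - 1 - 0.25 + 0.5))
        assert L3 == pytest.approx(2.0 * (3 - 1 + 0.25 - 0.5))
        assert L4 == pytest.approx(2.0 * (3 - 0.25 - 0.5))

    def test_all_below_k_dx(self):
        for k in (1, 2, 5):
            for xf in (0.1, 0.5, 0.9):
                for yf in (0.2, 0.8):
                    for L in class_lengths(k, xf, yf, 1.0):
                        assert L < k * 1.0

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidParameterError):
            class_lengths(0, 0.5, 0.5, 1.0)
        with pytest.raises(InvalidParameterError):
            class_lengths(1, 1.5, 0.5, 1.0)


class TestMatrixGreens:
    def test_matches_enumerated_series(self, y_dtree):
        """Matrix method == trip series at matched truncation (<= k edges)."""
        m = y_dtree.m
        x, y = m.point("AB", 0.3), m.point("BD", 0.6)
        t = time_grid(5 * m.tau, m.tau / 100)
        kmax = 13
        with pytest.warns(UserWarning):
            G = matrix_greens(y_dtree, x, y, t, kmax)
        trips = list(brute_force_walks(m, x, y, max_nodes=kmax - 1))
        S = greens_series(m, trips, x, y, t)
        assert relative_error(G, S) < 1e-10

    def test_grouped_coefficients_match_enumeration(self, y_dtree):
        """(Q^{k-1} c1)_g sums equal brute-force A_trip sums per length."""
        m = y_dtree.m
        x, y = m.point("AB", 0.3), m.point("BD", 0.6)
        kmax = 12
        trips = list(brute_force_walks(m, x, y, max_nodes=kmax - 1))
        enum_sums = defaultdict(float)
        for tr in trips:
            enum_sums[round(trip_length(m, tr), 9)] += trip_coefficient(m, tr)
        cm = build_q(y_dtree)
        s, xf, g, yf = _orient_start_goal(y_dtree, x, y)
        idx = {e: i for i, e in enumerate(cm.edges)}
        cs = np.zeros(6)
        cs[idx[s]] = 1.0
        csp = np.zeros(6)
        csp[idx[(s[1], s[0])]] = 1.0
        mat_sums = defaultdict(float)
        dx = y_dtree.dx
        for k in range(1, kmax + 1):
            L1, L2, L3, L4 = class_lengths(k, xf, yf, dx)
            mat_sums[round(L1, 9)] += cs[idx[g]]
            mat_sums[round(L2, 9)] += csp[idx[g]]
            mat_sums[round(L3, 9)] += cs[idx[(g[1], g[0])]]
            mat_sums[round(L4, 9)] += csp[idx[(g[1], g[0])]]
            cs = cm.Q @ cs
            csp = cm.Q @ csp
        for L, A in enum_sums.items():
            assert mat_sums[L] == pytest.approx(A, abs=1e-10)

    def test_grouped_coefficients_random_tree(self):
        """Same grouping identity on a random-topology tree with uniform
        electrotonic segment lengths but mixed diameters."""
        import random

        from dtrips.morphology import _build, derive_electrotonic

        rng = random.Random(13)
        params = CableParameters()
        # random topology; physical lengths chosen so every branch has
        # electrotonic length exactly 0.5
        edges = []
        tips = ["n0"]
        for i in range(8):
            tip = tips.pop(rng.randrange(len(tips)))
            a = rng.uniform(0.6, 1.6)
            lam, _, _, _ = derive_electrotonic(1.0, a, params)
            edges.append((f"b{i + 1}", tip, f"m{i + 1}", 0.5 * lam, a))
            tips.extend([f"m{i + 1}"] * (2 if len(tips) < 3 else 1))
        m0 = _build(edges, params, root="n0")
        dt = discretise(m0, 0.25)
        assert dt.max_distortion < 1e-12
        x = m0.point("b2", 0.3)
        y = m0.point("b7", 0.6)
        dm = dt.to_morphology()

        def on_dm(p):
            (u, v), frac = dt.locate(p)
            key = (u, v) if u < v else (v, u)
            return dm.point(f"{key[0]}~{key[1]}", frac if (u, v) == key else 1 - frac)

        xd, yd = on_dm(x), on_dm(y)
        kmax = 9
        # enumerate on the discretised morphology: each segment is a branch
        trips = list(brute_force_walks(dm, xd, yd, max_nodes=kmax - 1))
        assert trips, "budget admits at least the direct trip"
        enum_sums = defaultdict(float)
        for tr in trips:
            enum_sums[round(trip_length(dm, tr), 9)] += trip_coefficient(dm, tr)
        cm = build_q(dt)
        s, xf, g, yf = _orient_start_goal(dt, x, y)
        idx = {e: i for i, e in enumerate(cm.edges)}
        cs = np.zeros(len(cm.edges))
        cs[idx[s]] = 1.0
        csp = np.zeros(len(cm.edges))
        csp[idx[(s[1], s[0])]] = 1.0
        mat_sums = defaultdict(float)
        for k in range(1, kmax + 1):
            L1, L2, L3, L4 = class_lengths(k, xf, yf, dt.dx)
            mat_sums[round(L1, 9)] += cs[idx[g]]
            mat_sums[round(L2, 9)] += csp[idx[g]]
            mat_sums[round(L3, 9)] += cs[idx[(g[1], g[0])]]
            mat_sums[round(L4, 9)] += csp[idx[(g[1], g[0])]]
            cs = cm.Q @ cs
            csp = cm.Q @ csp
        for L, A in enum_sums.items():
            assert mat_sums[L] == pytest.approx(A, abs=1e-9)

    def test_same_edge_rediscretised(self):
        """x and y on one edge: the tree is refined until they separate; the
        result agrees with the independent finite-difference solution."""
        from dtrips import solve_cable_cn

        m = make_y_tree(100.0, 1.0, CableParameters())
        dt = discretise(m, m.el("AB"))
        x, y = m.point("AB", 0.2), m.point("AB", 0.8)
        # fine dt: the nearby impulse makes the early response sharp
        t = time_grid(5 * m.tau, m.tau / 400)
        G = matrix_greens(dt, x, y, t, kmax=240)
        assert G.meta["dx"] < dt.dx  # re-discretised
        sol = solve_cable_cn(m, y, t, points=[x], dx_el=0.005)
        assert relative_error(G, sol) < 1e-3

    def test_whole_tree_sweep_matches_single_target(self):
        m = make_y_tree(100.0, 1.0, CableParameters())
        dt = discretise(m, m.el("AB") / 2.0)
        x = m.point("AB", 0.25)
        t = time_grid(5 * m.tau, m.tau / 100)
        allG = matrix_greens_all(dt, x, t, kmax=80, y_fraction=0.5)
        for key, G in list(allG.items())[:4]:
            single = matrix_greens(dt, x, G.y, t, kmax=80)
            assert relative_error(G, single) < 1e-12

    def test_self_convergence(self, tree_a3):
        """Doubling kmax beyond the diffusion range changes nothing: the
        truncation error is below 1e-15."""
        m = tree_a3
        dt = discretise(m, m.el("2"))
        x, y = m.point("4", 0.5), m.point("10", 0.5)
        t = time_grid(5 * m.tau, m.tau / 100)
        G1 = matrix_greens(dt, x, y, t, kmax=150)
        G2 = matrix_greens(dt, x, y, t, kmax=300)
        assert relative_error(G1, G2) <= 1e-15
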