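import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dtrips import (
    CableParameters,
    InvalidParameterError,
    TripError,
    appendix_bound,
    convergence_bound,
    ginf,
    greens_series,
    make_cable,
    make_trip,
    make_y_tree,
    node_factor,
    reciprocal,
    time_grid,
    trip_coefficient,
    trip_length,
    voltage_response,
)
from dtrips.core import source_prefactor
from dtrips.enumeration import brute_force_walks, enumerate_length_priority


class TestNodeFactor:
    def test_symmetric_junction(self, y_tree):
        for b in ("AB", "BC", "BD"):
            assert node_factor(y_tree, "B", b) == pytest.approx(1 / 3)

    def test_unequal_diameters(self):
        """Diameters (2, 1, 1): p_big = 2^{3/2}/(2^{3/2} + 2) = 2 - sqrt(2)."""
        p = CableParameters()
        from dtrips.morphology import _build

        m = _build(
            [("big", "A", "B", 50.0, 2.0), ("s1", "B", "C", 50.0, 1.0),
             ("s2", "B", "D", 50.0, 1.0)],
            p, root="A",
        )
        assert node_factor(m, "B", "big") == pytest.approx(2 - math.sqrt(2))

    @given(
        diams=st.tuples(*[st.floats(0.2, 5.0)] * 3),
    )
    def test_normalisation_and_form_equivalence(self, diams):
        """Sum of p over incident branches is 1, and the conductance form
        (lambda r)^-1 reduces to the a^{3/2} form for uniform membrane."""
        from dtrips.morphology import _build

        p = CableParameters()
        m = _build(
            [(f"b{i}", "A" if i == 0 else "B", "B" if i == 0 else f"T{i}",
              50.0, d) for i, d in enumerate(diams)],
            p, root="A",
        )
        ps = [node_factor(m, "B", f"b{i}") for i in range(3)]
        assert sum(ps) == pytest.approx(1.0, abs=1e-12)
        for i, d in enumerate(diams):
            b = m.branches[f"b{i}"]
            cond = [1.0 / (m.branches[f"b{j}"].lam * m.branches[f"b{j}"].r)
                    for j in range(3)]
            assert ps[i] == pytest.approx(cond[i] / sum(cond), rel=1e-12)

    def test_non_incident_branch_is_error(self, y_tree):
        with pytest.raises(TripError):
            node_factor(y_tree, "A", "BD")


class TestGinf:
    def test_value_at_origin(self):
        """Ginf(0, t=tau=1, D=1) = e^{-1}/sqrt(4 pi)."""
        assert ginf(0.0, 1.0, 1.0, 1.0) == pytest.approx(
            math.exp(-1) / math.sqrt(4 * math.pi)
        )

    def test_zero_limit_at_t0(self):
        assert ginf(1.0, 0.0, 1.0, 1.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            ginf(1.0, -0.1, 1.0, 1.0)

    @given(L=st.floats(0.1, 5.0), t=st.floats(0.01, 20.0),
           lam=st.floats(50.0, 500.0), tau=st.floats(1.0, 20.0))
    def test_physical_length_equivalence(self, L, t, lam, tau):
        """The electrotonic form equals the physical-length Gaussian
        (4 pi t D)^{-1/2} exp(-Lphys^2/(4 D t)) exp(-t/tau)."""
        D = lam * lam / tau
        Lphys = L * lam
        expected = (math.exp(-Lphys * Lphys / (4 * D * t) - t / tau)
                    / math.sqrt(4 * math.pi * t * D))
        assert ginf(L, t, D, tau) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_length(self):
        t = 2.0
        vals = [ginf(L, t, 1.0, 1.0) for L in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestTrips:
    def test_pass_through_coefficient(self, y_tree):
        """x on AB, y on BD, trip xBy: 2 p = 2/3."""
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        t = make_trip(y_tree, ("B",), x, y)
        assert trip_coefficient(y_tree, t) == pytest.approx(2 / 3)

    def test_reflect_terminal_pass_coefficient(self, y_tree):
        """Trip xBABy: (2p-1) * (+1) * 2p = -2/9."""
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        t = make_trip(y_tree, ("B", "A", "B"), x, y)
        assert trip_coefficient(y_tree, t) == pytest.approx(-2 / 9)

    def test_coefficient_bound(self, double_junction_tree):
        """|A_trip| <= 2^k for any trip visiting k nodes."""
        x, y = double_junction_tree.point("AB", 0.3), double_junction_tree.point("BC", 0.6)
        for trip in brute_force_walks(double_junction_tree, x, y, max_nodes=7):
            k = len(trip.nodes)
            assert abs(trip_coefficient(double_junction_tree, trip)) <= 2.0 ** k + 1e-12

    def test_direct_length(self, cable):
        x, y = cable.point("seg1", 0.2), cable.point("seg1", 0.7)
        t = make_trip(cable, (), x, y)
        el = cable.el("seg1")
        assert trip_length(cable, t) == pytest.approx(0.5 * el)

    def test_reflected_length(self, cable):
        """Reflect at the distal node from x=0.2, return to y=0.7."""
        x, y = cable.point("seg1", 0.2), cable.point("seg1", 0.7)
        t = make_trip(cable, ("1",), x, y)
        el = cable.el("seg1")
        assert trip_length(cable, t) == pytest.approx((0.8 + 0.3) * el)

    def test_length_invariant_under_refinement(self, params):
        """Splitting a branch into collinear sub-branches of the same
        diameter leaves trip lengths unchanged."""
        m1 = make_cable(300.0, 1.0, params, n_segments=1)
        m3 = make_cable(300.0, 1.0, params, n_segments=3)
        x1, y1 = m1.point("seg1", 0.1), m1.point("seg1", 0.9)
        # same physical points on the refined cable
        x3, y3 = m3.point("seg1", 0.3), m3.point("seg3", 0.7)
        t1 = make_trip(m1, ("1",), x1, y1)           # reflect at the far end
        t3 = make_trip(m3, ("1", "2", "3"), x3, y3)
        assert trip_length(m1, t1) == pytest.approx(trip_length(m3, t3))

    def test_invalid_sequence_rejected(self, y_tree):
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        with pytest.raises(TripError):
            make_trip(y_tree, ("C",), x, y)
        with pytest.raises((TripError, KeyError)):
            make_trip(y_tree, ("B", "A", "D"), x, y)


class TestSeries:
    def test_single_trip_equals_free_space(self, params):
        """On an effectively infinite cable the one-trip series is the
        free-space kernel with the 1/(pi a C) prefactor."""
        m = make_cable(5000.0, 1.0, params)
        x, y = m.point("seg1", 0.45), m.point("seg1", 0.55)
        t = time_grid(10.0, 0.1)
        G = greens_series(m, [make_trip(m, (), x, y)], x, y, t)
        b = m.branches["seg1"]
        expected = source_prefactor(m, "seg1") * ginf(
            0.1 * m.el("seg1"), t, b.D, b.tau
        )
        assert np.allclose(G.values, expected, rtol=1e-12)

    def test_images_oracle(self, cable):
        """Truncated trip series matches the method-of-images solution for a
        sealed finite cable to 1e-8 relative L1."""
        m = cable
        el = m.el("seg1")
        x, y = m.point("seg1", 0.3), m.point("seg1", 0.7)
        t = time_grid(5 * m.tau, m.tau / 100)
        trips = list(brute_force_walks(m, x, y, max_nodes=30))
        G = greens_series(m, trips, x, y, t)
        b = m.branches["seg1"]
        X, Y = 0.3 * el, 0.7 * el
        img = np.zeros_like(t)
        for n in range(-60, 61):
            img += ginf(abs(X - Y + 2 * n * el), t, b.D, b.tau)
            img += ginf(abs(X + Y + 2 * n * el), t, b.D, b.tau)
        img *= source_prefactor(m, "seg1")
        rel = np.trapezoid(np.abs(G.values - img), t) / np.trapezoid(img, t)
        assert rel < 1e-8

    def test_zero_coefficient_trip_is_noop(self, cable):
        """A trip reflecting at an interior degree-2 node has 2p - 1 = 0."""
        m = make_cable(500.0, 1.0, cable.params, n_segments=2)
        x, y = m.point("seg1", 0.2), m.point("seg1", 0.8)
        t = time_grid(5.0, 0.1)
        base = [make_trip(m, (), x, y)]
        withzero = base + [make_trip(m, ("1",), x, y)]
        G1 = greens_series(m, base, x, y, t)
        G2 = greens_series(m, withzero, x, y, t)
        assert np.array_equal(G1.values, G2.values)

    def test_empty_trip_set_warns(self, y_tree):
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        t = time_grid(5.0, 0.5)
        with pytest.warns(UserWarning):
            G = greens_series(y_tree, [], x, y, t)
        assert np.all(G.values == 0.0)


class TestReciprocity:
    def _series(self, m, x, y, t):
        # truncate by length so both directions keep whole tie classes
        cutoff = 8.0 * max(m.el(b) for b in m.branches)
        trips = list(enumerate_length_priority(m, x, y, max_length=cutoff))
        return greens_series(m, trips, x, y, t)

    def test_equal_diameters_symmetric(self, y_tree):
        t = time_grid(10.0, 0.25)
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        Gxy = self._series(y_tree, x, y, t)
        Gyx = self._series(y_tree, y, x, t)
        assert np.allclose(reciprocal(Gxy, y_tree).values, Gyx.values, rtol=1e-9)

    def test_unequal_diameters_scale(self):
        from dtrips.morphology import _build

        m = _build(
            [("thick", "A", "B", 60.0, 2.0), ("thin", "B", "C", 60.0, 1.0),
             ("side", "B", "D", 60.0, 1.0)],
            CableParameters(), root="A",
        )
        t = time_grid(10.0, 0.25)
        x, y = m.point("thick", 0.5), m.point("thin", 0.5)
        Gxy = self._series(m, x, y, t)
        Gyx = self._series(m, y, x, t)
        # the bare kernels differ by (D_j r_j)/(D_i r_i); the voltage
        # Green's function, prefactor included, is symmetric
        assert np.allclose(reciprocal(Gxy, m).values, Gyx.values, rtol=1e-8)
        bi, bj = m.branches["thick"], m.branches["thin"]
        Hxy = Gxy.values * (math.pi * bj.a)
        Hyx = Gyx.values * (math.pi * bi.a)
        scale = (bj.D * bj.r) / (bi.D * bi.r)
        assert np.allclose(scale * Hxy, Hyx, rtol=1e-8)

    def test_double_application_is_identity(self, y_tree):
        t = time_grid(10.0, 0.25)
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        G = self._series(y_tree, x, y, t)
        GG = reciprocal(reciprocal(G, y_tree), y_tree)
        assert np.allclose(G.values, GG.values, rtol=1e-12)
        assert GG.x == G.x and GG.y == G.y


class TestVoltageResponse:
    def _greens(self, y_tree, t):
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        trips = list(enumerate_length_priority(y_tree, x, y, n_trips=100))
        return greens_series(y_tree, trips, x, y, t)

    def test_discrete_impulse_recovers_kernel(self, y_tree):
        t = time_grid(10.0, 0.01)
        G = self._greens(y_tree, t)
        I = np.zeros_like(t)
        I[0] = 2.0 / (t[1] - t[0])   # trapezoid-weight discrete delta
        V = voltage_response(y_tree, [G], [I], t)
        # O(dt) agreement away from the initial transient
        mask = t > 1.0
        assert np.allclose(V[mask], G.values[mask], rtol=2e-2, atol=1e-12)

    def test_linearity(self, y_tree):
        t = time_grid(10.0, 0.05)
        G = self._greens(y_tree, t)
        I = np.exp(-t)
        V1 = voltage_response(y_tree, [G], [I], t)
        V2 = voltage_response(y_tree, [G, G], [I, I], t)
        assert np.allclose(V2, 2 * V1, rtol=1e-12)

    def test_step_current_is_cumulative_integral(self, y_tree):
        """V for a unit step equals the running integral of G."""
        t = time_grid(10.0, 0.01)
        G = self._greens(y_tree, t)
        I = np.ones_like(t)
        V = voltage_response(y_tree, [G], [I], t)
        from scipy.integrate import cumulative_trapezoid

        expected = cumulative_trapezoid(G.values, t, initial=0.0)
        assert np.allclose(V, expected, rtol=1e-10, atol=1e-14)

    def test_grid_mismatch_rejected(self, y_tree):
        t = time_grid(10.0, 0.05)
        G = self._greens(y_tree, t)
        with pytest.raises(InvalidParameterError):
            voltage_response(y_tree, [G], [np.ones(7)], t)


class TestAppendixBound:
    def test_k0_equals_constant(self, y_tree):
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        b = convergence_bound(y_tree, x, y, t=2.0)
        assert appendix_bound(0, b) == pytest.approx(b.Cconst)

    def test_decreasing_beyond_n(self, y_tree):
        x, y = y_tree.point("AB", 0.3), y_tree.point("BD", 0.6)
        b = convergence_bound(y_tree, x, y, t=2.0)
        ks = range(b.N + 1, b.N + 20)
        vals = [appendix_bound(k, b) for k in ks]
        assert all(u > v for u, v in zip(vals, vals[1:]))

    @pytest.mark.parametrize("frac", [0.3, 0.62])
    def test_dominates_enumerated_terms(self, y_tree, frac):
        """Cconst e^{-k(E B^2 k - ln 6)} >= |Gamma_k| from brute force."""
        x, y = y_tree.point("AB", frac), y_tree.point("BD", 0.55)
        tval = 2.0
        b = convergence_bound(y_tree, x, y, t=tval)
        gammas = {}
        bj = y_tree.branches["BD"]
        for trip in brute_force_walks(y_tree, x, y, max_nodes=10):
            k = len(trip.nodes)
            term = trip_coefficient(y_tree, trip) * ginf(
                trip_length(y_tree, trip), tval, bj.D, bj.tau
            )
            gammas[k] = gammas.get(k, 0.0) + term
        for k, g in gammas.items():
            assert abs(g) <= appendix_bound(k, b) * (1 + 1e-12)

    def test_high_degree_rejected(self):
        from dtrips.morphology import _build

        m = _build(
            [(f"b{i}", "hub", f"T{i}", 50.0, 1.0) for i in range(4)],
            CableParameters(), root="T0",
        )
        with pytest.raises(InvalidParameterError):
            convergence_bound(m, m.point("b0", 0.5), m.point("b1", 0.5), t=1.0)

    def test_partial_sums_cauchy(self, tree_a3):
        """Beyond N the tail of the series is bounded by the summed bound."""
        m = tree_a3
        x, y = m.point("4", 0.5), m.point("10", 0.5)
        tval = 0.01   # early time: the bound starts decaying at small N
        b = convergence_bound(m, x, y, tval)
        bj = m.branches[y.branch]
        gammas = {}
        for trip in brute_force_walks(m, x, y, max_nodes=9):
            k = len(trip.nodes)
            gammas[k] = gammas.get(k, 0.0) + trip_coefficient(m, trip) * ginf(
                trip_length(m, trip), tval, bj.D, bj.tau
            )
        ks = sorted(gammas)
        for start in ks:
            if start <= b.N:
                continue
            tail = sum(abs(gammas[k]) for k in ks if k >= start)
            bound_tail = sum(appendix_bound(k, b) for k in range(start, 200))
            assert tail <= bound_tail * (1 + 1e-9)
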