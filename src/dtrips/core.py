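"""Sum-over-trips core: node factors, trip coefficients, series assembly.

The Green's function of the passive branched cable is expanded as

    G_ij(x, y, t) = 1/(pi a_j C) * sum_trips A_trip * Ginf(L_trip, t),

where the sum runs over all walks ("trips") on the tree from the measurement
point x on branch i to the injection point y on branch j,

    Ginf(L, t) = (4 pi t D_j)^(-1/2) exp(-L^2 tau / (4 t)) exp(-t / tau),

L_trip is the electrotonic trip length (every traversed segment divided by
its branch's space constant), and A_trip is a product of node factors: 2 p_k
for passing onto branch k, 2 p_n - 1 for reflecting back onto branch n at an
internal node, and +1 / -1 for reflecting at a closed / open terminal.

With all quantities in the package's internal units (um, ms, uF cm^-2) the
series value multiplied by ``MV_PER_NA_MS`` gives the response in mV to an
impulse of unit charge 1 nA ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple
import warnings

import numpy as np

from .morphology import InvalidParameterError, Morphology, PointOnBranch

__all__ = [
    "MV_PER_NA_MS",
    "TripError",
    "Trip",
    "GreensSeries",
    "ConvergenceBound",
    "node_factor",
    "ginf",
    "trip_coefficient",
    "trip_length",
    "make_trip",
    "greens_series",
    "reciprocal",
    "voltage_response",
    "time_grid",
    "convergence_bound",
    "appendix_bound",
]

#: Conversion of the internal Green's-function value (1/(pi a C) Ginf with a
#: in um, C in uF cm^-2, Ginf in um^-1) to mV per nA ms of injected charge.
MV_PER_NA_MS = 1e5


class TripError(ValueError):
    """Raised for node sequences that are not valid walks on the tree."""


def node_factor(m: Morphology, node_id: str, branch_id: str) -> float:
    """Node factor p_k of ``branch_id`` at ``node_id``.

    With uniform membrane parameters p_k = a_k^(3/2) / sum_m a_m^(3/2);
    with per-branch R or Ra it generalises to
    p_k = (lambda_k r_k)^-1 / sum_m (lambda_m r_m)^-1.  The factors over the
    incident branches of a node sum to one.
    """
    key = (node_id, branch_id)
    cached = m._pcache.get(key)
    if cached is not None:
        return cached
    incident = m.incident_branches(node_id)
    if branch_id not in incident:
        raise TripError(f"branch {branch_id!r} is not incident to node {node_id!r}")
    if m.params.uniform:
        weights = {b: m.branches[b].a ** 1.5 for b in incident}
    else:
        weights = {
            b: 1.0 / (m.branches[b].lam * m.branches[b].r) for b in incident
        }
    total = sum(weights.values())
    for b in incident:
        m._pcache[(node_id, b)] = weights[b] / total
    return m._pcache[key]


def ginf(L: float, t, D: float, tau: float):
    """Free-space Gaussian kernel Ginf(L, t) for electrotonic length L.

    Accepts scalar or array ``t`` (ms); returns the limit 0 at t = 0 for
    L > 0.  Negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("negative time passed to ginf")
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    with np.errstate(divide="ignore"):
        out[pos] = (
            np.exp(-(L * L) * tau / (4.0 * tp) - tp / tau)
            / np.sqrt(4.0 * math.pi * tp * D)
        )
    if np.any(~pos) and L == 0.0:
        out[~pos] = np.inf
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Trip:
    """A walk from x to y described by its intermediate node sequence."""

    nodes: Tuple[str, ...]
    x: PointOnBranch
    y: PointOnBranch

    def __len__(self) -> int:
        return len(self.nodes)


def _check_trip(m: Morphology, trip: Trip) -> None:
    nodes = trip.nodes
    if nodes:
        first_ok = nodes[0] in m.endpoints(trip.x.branch)
        last_ok = nodes[-1] in m.endpoints(trip.y.branch)
        if not first_ok:
            raise TripError(
                f"first node {nodes[0]!r} is not an endpoint of branch {trip.x.branch!r}"
            )
        if not last_ok:
            raise TripError(
                f"last node {nodes[-1]!r} is not an endpoint of branch {trip.y.branch!r}"
            )
        for u, v in zip(nodes, nodes[1:]):
            m.branch_between(u, v)  # raises KeyError if not adjacent
    elif trip.x.branch != trip.y.branch:
        raise TripError("empty node sequence requires x and y on the same branch")


def trip_length(m: Morphology, trip: Trip) -> float:
    """Electrotonic length of a trip (each segment scaled by its lambda)."""
    _check_trip(m, trip)
    nodes = trip.nodes
    if not nodes:
        return abs(trip.x.fraction - trip.y.fraction) * m.el(trip.x.branch)
    length = m.point_segments(trip.x)[nodes[0]]
    for u, v in zip(nodes, nodes[1:]):
        length += m.el(m.branch_between(u, v))
    length += m.point_segments(trip.y)[nodes[-1]]
    return length


def trip_coefficient(m: Morphology, trip: Trip) -> float:
    """Coefficient A_trip: product of pass/reflect/terminal node factors."""
    key = (trip.x.branch, trip.nodes, trip.y.branch)
    cached = m._coeff_cache.get(key)
    if cached is not None:
        return cached
    _check_trip(m, trip)
    coeff = 1.0
    prev_branch = trip.x.branch
    nodes = trip.nodes
    for idx, n in enumerate(nodes):
        if idx + 1 < len(nodes):
            next_branch = m.branch_between(n, nodes[idx + 1])
        else:
            next_branch = trip.y.branch
        if m.is_terminal(n):
            coeff *= m.terminal_sign(n)
        elif next_branch == prev_branch:
            coeff *= 2.0 * node_factor(m, n, next_branch) - 1.0
        else:
            coeff *= 2.0 * node_factor(m, n, next_branch)
        prev_branch = next_branch
    m._coeff_cache[key] = coeff
    return coeff


def make_trip(
    m: Morphology, nodes: Sequence[str], x: PointOnBranch, y: PointOnBranch
) -> Trip:
    """Validated Trip constructor."""
    trip = Trip(tuple(nodes), x, y)
    _check_trip(m, trip)
    return trip


# -- series assembly ----------------------------------------------------


def time_grid(T: float, dt: float) -> np.ndarray:
    """Uniform time grid 0, dt, ..., T (inclusive within rounding)."""
    if T <= 0 or dt <= 0:
        raise InvalidParameterError("T and dt must be positive")
    n = int(round(T / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _check_uniform(t: np.ndarray) -> float:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise InvalidParameterError("time grid needs at least two points")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        raise InvalidParameterError("time grid must be strictly increasing and uniform")
    return float(dt[0])


@dataclass
class GreensSeries:
    """A Green's function sampled on a uniform time grid."""

    t: np.ndarray
    values: np.ndarray
    x: PointOnBranch
    y: PointOnBranch
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise InvalidParameterError("time grid and values have different shapes")

    @property
    def dt(self) -> float:
        return _check_uniform(self.t)

    def scaled(self, factor: float) -> "GreensSeries":
        return GreensSeries(self.t, self.values * factor, self.x, self.y, dict(self.meta))


def source_prefactor(m: Morphology, branch_id: str) -> float:
    """1/(pi a_j C_j) for the injection branch."""
    C, _, _ = m.params.membrane(branch_id)
    return 1.0 / (math.pi * m.branches[branch_id].a * C)


def greens_series(
    m: Morphology,
    trips: Sequence[Trip],
    x: PointOnBranch,
    y: PointOnBranch,
    t: np.ndarray,
) -> GreensSeries:
    """Assemble the truncated series over the given trips on grid ``t``."""
    t = np.asarray(t, dtype=float)
    bj = m.branches[y.branch]
    values = np.zeros_like(t)
    if not trips:
        warnings.warn("empty trip set: returning a zero Green's function")
    for trip in trips:
        if trip.x != x or trip.y != y:
            raise TripError("all trips must share the endpoints x, y")
        A = trip_coefficient(m, trip)
        if A == 0.0:
            continue
        values += A * ginf(trip_length(m, trip), t, bj.D, bj.tau)
    values *= source_prefactor(m, y.branch)
    return GreensSeries(t, values, x, y, {"method": "series", "n_trips": len(trips)})


def reciprocal(G: GreensSeries, m: Morphology) -> GreensSeries:
    """Swap measurement and injection points via reciprocity.

    The bare trip sums H = sum A_trip Ginf satisfy the kernel identity
    H_ji(y, x) = (D_j r_j)/(D_i r_i) H_ij(x, y); together with the source
    prefactors 1/(pi a C) the voltage Green's function obeys

        G_ji(y, x, t) = (a_j C_j)/(a_i C_i) * (D_j r_j)/(D_i r_i) * G_ij,

    which is exactly symmetric for uniform membrane (D r scales as 1/(a C)),
    as required of the transfer impedance of a reciprocal passive network;
    the enumeration oracle confirms the symmetry.
    """
    bi = m.branches[G.x.branch]
    bj = m.branches[G.y.branch]
    Ci = m.params.membrane(bi.id)[0]
    Cj = m.params.membrane(bj.id)[0]
    scale = (bj.a * Cj * bj.D * bj.r) / (bi.a * Ci * bi.D * bi.r)
    out = G.scaled(scale)
    out.x, out.y = G.y, G.x
    out.meta["reciprocal"] = True
    return out


def voltage_response(
    m: Morphology,
    greens: Sequence[GreensSeries],
    currents: Sequence[np.ndarray],
    t: np.ndarray,
) -> np.ndarray:
    """Voltage V(x, t) = sum_j int_0^t G_j(t - s) I_j(s) ds (trapezoid).

    ``greens[j]`` is the kernel from stimulus site j to the common
    measurement point; ``currents[j]`` is sampled on the same grid ``t``.
    """
    t = np.asarray(t, dtype=float)
    dt = _check_uniform(t)
    n = len(t)
    if len(greens) != len(currents):
        raise InvalidParameterError("need one current per Green's function")
    V = np.zeros(n)
    for G, I in zip(greens, currents):
        I = np.asarray(I, dtype=float)
        if G.t.shape != t.shape or not np.allclose(G.t, t):
            raise InvalidParameterError("Green's function grid does not match t")
        if I.shape != t.shape:
            raise InvalidParameterError("current grid does not match t")
        g = G.values
        conv = np.convolve(g, I)[:n] * dt
        # trapezoid end-point correction
        conv -= 0.5 * dt * (g * I[0] + g[0] * I)
        V += conv
    return V


# -- Appendix convergence bound -----------------------------------------


@dataclass(frozen=True)
class ConvergenceBound:
    """Constants of the tail bound |Gamma_k| <= Cconst exp(-k (E B^2 k - ln 6)).

    B is the minimum internode (electrotonic) distance, with x and y counted
    as nodes; Cconst = e^(-t/tau)/sqrt(4 pi D t); E = 1/(4 D t);
    N = floor(ln 6 / (E B^2)) marks where the bound starts to decay.
    """

    B: float
    Cconst: float
    E: float

    def __post_init__(self) -> None:
        if self.B <= 0 or self.Cconst <= 0 or self.E <= 0:
            raise InvalidParameterError("bound constants must be positive")

    @property
    def N(self) -> int:
        return int(math.floor(math.log(6.0) / (self.E * self.B * self.B)))


def convergence_bound(
    m: Morphology, x: PointOnBranch, y: PointOnBranch, t: float
) -> ConvergenceBound:
    """Construct the tail-bound constants for a tree at a fixed time t.

    Requires node degree <= 3 everywhere (the trip count F_k <= 3^k step) and
    a uniform diffusion coefficient across branches.  Lengths are handled in
    electrotonic units, so E = tau/(4t) while the amplitude constant keeps
    the physical diffusion coefficient of the Gaussian prefactor.
    """
    if t <= 0:
        raise InvalidParameterError("t must be positive")
    for nid in m.nodes:
        if m.degree(nid) > 3:
            raise InvalidParameterError(
                f"node {nid!r} has degree {m.degree(nid)} > 3: the 3^k trip-count "
                "bound does not apply"
            )
    tau = m.tau
    Ds = {b.D for b in m.branches.values()}
    Dphys = Ds.pop()
    if Ds and any(abs(d - Dphys) > 1e-9 * Dphys for d in Ds):
        raise InvalidParameterError("tail bound requires a uniform diffusion coefficient")
    candidates = [m.el(b) for b in m.branches]
    for p in (x, y):
        candidates.extend(v for v in m.point_segments(p).values() if v > 0)
    if x.branch == y.branch:
        d = abs(x.fraction - y.fraction) * m.el(x.branch)
        if d > 0:
            candidates.append(d)
    B = min(candidates)
    Cconst = math.exp(-t / tau) / math.sqrt(4.0 * math.pi * Dphys * t)
    E = tau / (4.0 * t)  # 1/(4 D t) with electrotonic lengths, D -> 1/tau
    return ConvergenceBound(B=B, Cconst=Cconst, E=E)


def appendix_bound(k: int, bound: ConvergenceBound) -> float:
    """Upper bound on |Gamma_k|, the summed k-node term of the series."""
    if k < 0:
        raise InvalidParameterError("k must be non-negative")
    return bound.Cconst * math.exp(-k * (bound.E * bound.B * bound.B * k - math.log(6.0)))
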