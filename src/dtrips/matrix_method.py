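"""Matrix method: trips grouped by length on a uniformly discretised tree.

Every branch is replaced by an integer number of edges of common electrotonic
length dx.  Trips from x (on start edge s) to y (on goal edge g) then fall
into four classes by their departure/arrival directions, and all trips of a
class travelling k edges share a common length (see ``class_lengths``)
determined by the fractional positions x, y along s and g (x dx = distance
x -> s2, y dx = distance g1 -> y).  The summed coefficient of each group is obtained
by iterating c_{k+1} = Q c_k, where Q is the modified directed-edge
adjacency matrix: Q[i, j] is the coefficient taken when moving from edge e_j
to edge e_i (2 p for a pass-through, 2 p - 1 for a reflection, +/-1 at
terminals; for equal radii and degree <= 3 these are 2/3, -1/3 and 1).
Q is sparse with O(|E|) entries, so kmax steps cost O(|E| kmax).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .core import GreensSeries, ginf, source_prefactor
from .enumeration import nudge_off_node
from .morphology import (
    Branch,
    InvalidParameterError,
    Morphology,
    Node,
    PointOnBranch,
)

__all__ = [
    "DiscretisedTree",
    "CoefficientMatrix",
    "discretise",
    "build_q",
    "class_lengths",
    "matrix_greens",
    "matrix_greens_all",
]


@dataclass
class DiscretisedTree:
    """A morphology re-expressed as edges of uniform electrotonic length.

    ``edges`` lists both orientations of every undirected segment; segment
    nodes are the original nodes plus inserted intermediates named
    "branchid#i".  ``of_branch`` maps each undirected segment (u, v) with
    u < v to the underlying branch id.
    """

    m: Morphology
    dx: float                                  # electrotonic edge length
    edges: List[Tuple[str, str]]
    index: Dict[Tuple[str, str], int]
    neighbors: Dict[str, List[str]]
    of_branch: Dict[Tuple[str, str], str]
    n_per_branch: Dict[str, int]
    max_distortion: float

    def reverse(self, e: Tuple[str, str]) -> Tuple[str, str]:
        return (e[1], e[0])

    def degree(self, node: str) -> int:
        return len(self.neighbors[node])

    def is_terminal(self, node: str) -> bool:
        return node in self.m.nodes and self.m.is_terminal(node)

    def segment_branch(self, u: str, v: str) -> str:
        return self.of_branch[(u, v) if u < v else (v, u)]

    def diameter(self, u: str, v: str) -> float:
        return self.m.branches[self.segment_branch(u, v)].a

    def to_morphology(self) -> Morphology:
        """Express the discretised tree as a Morphology (segments = branches).

        Used by the oracle tests: trips enumerated on this morphology group
        exactly into the matrix method's length classes.
        """
        seen = set()
        node_ids = set()
        branches = []
        for (u, v) in self.edges:
            key = (u, v) if u < v else (v, u)
            if key in seen:
                continue
            seen.add(key)
            node_ids.update(key)
            b = self.m.branches[self.of_branch[key]]
            n = self.n_per_branch[b.id]
            branches.append(
                Branch(
                    id=f"{key[0]}~{key[1]}",
                    proximal=key[0],
                    distal=key[1],
                    L=b.L / n,
                    a=b.a,
                    lam=b.lam,
                    D=b.D,
                    tau=b.tau,
                    r=b.r,
                )
            )
        nodes = []
        for nid in sorted(node_ids):
            deg = sum(1 for b in branches if nid in (b.proximal, b.distal))
            if deg == 1:
                orig = self.m.nodes.get(nid)
                boundary = orig.boundary if orig is not None else self.m.params.boundary
                nodes.append(Node(nid, "terminal", boundary))
            else:
                nodes.append(Node(nid, "internal"))
        root = self.m.root if self.m.root in node_ids else nodes[0].id
        return Morphology(nodes, branches, self.m.params, root)

    def locate(self, p: PointOnBranch) -> Tuple[Tuple[str, str], float]:
        """Segment containing p (oriented proximal->distal) and the fraction
        of p along that segment."""
        b = self.m.branches[p.branch]
        n = self.n_per_branch[p.branch]
        pos = p.fraction * n
        i = min(int(pos), n - 1)
        frac = pos - i
        chain = self.branch_chain(p.branch)
        return (chain[i], chain[i + 1]), frac

    def branch_chain(self, branch_id: str) -> List[str]:
        """Node chain of a branch from proximal to distal."""
        b = self.m.branches[branch_id]
        n = self.n_per_branch[branch_id]
        if n == 1:
            return [b.proximal, b.distal]
        return [b.proximal] + [f"{branch_id}#{i}" for i in range(1, n)] + [b.distal]


def discretise(
    m: Morphology, dx: float, split_branches: Optional[Dict[str, int]] = None
) -> DiscretisedTree:
    """Discretise every branch into round(el/dx) >= 1 uniform edges.

    ``dx`` is an electrotonic step; the realised per-branch step el/n may
    deviate from dx when branch lengths are not multiples of it, and the
    maximum relative deviation is reported as ``max_distortion``.
    ``split_branches`` forces a minimum edge count on selected branches
    (used to separate x from y when they share an edge).
    """
    if dx <= 0:
        raise InvalidParameterError("dx must be positive")
    min_el = min(m.el(b) for b in m.branches)
    if dx > 2.0 * min_el:
        warnings.warn(
            f"dx={dx:g} exceeds twice the shortest branch ({min_el:g}); "
            "the discretisation will be badly distorted"
        )
    split_branches = split_branches or {}
    n_per_branch: Dict[str, int] = {}
    max_dist = 0.0
    for bid in m.branches:
        el = m.el(bid)
        n = max(1, int(round(el / dx)), split_branches.get(bid, 1))
        n_per_branch[bid] = n
        max_dist = max(max_dist, abs(el / n - dx) / dx)
    edges: List[Tuple[str, str]] = []
    of_branch: Dict[Tuple[str, str], str] = {}
    neighbors: Dict[str, List[str]] = {}
    dt = DiscretisedTree(m, dx, edges, {}, neighbors, of_branch, n_per_branch, max_dist)
    for bid in sorted(m.branches):
        chain = dt.branch_chain(bid)
        for u, v in zip(chain, chain[1:]):
            key = (u, v) if u < v else (v, u)
            of_branch[key] = bid
            edges.append((u, v))
            edges.append((v, u))
            neighbors.setdefault(u, []).append(v)
            neighbors.setdefault(v, []).append(u)
    edges.sort()
    dt.index = {e: i for i, e in enumerate(edges)}
    for lst in neighbors.values():
        lst.sort()
    return dt


@dataclass
class CoefficientMatrix:
    """Q with the step coefficients; ``Q[i, j]`` moves from edge j to edge i."""

    Q: sp.csr_matrix
    edges: List[Tuple[str, str]]
    exact: Optional[np.ndarray] = None   # object array of Fractions, if built

    def indicator(self, e: Tuple[str, str]) -> np.ndarray:
        c = np.zeros(len(self.edges))
        c[self.edges.index(e)] = 1.0
        return c


def _dtree_node_factor(dt: DiscretisedTree, node: str, towards: str):
    """Node factor of the segment node->towards among segments at ``node``."""
    m = dt.m
    nbrs = dt.neighbors[node]
    if m.params.uniform:
        weights = [dt.diameter(node, nb) ** 1.5 for nb in nbrs]
    else:
        weights = []
        for nb in nbrs:
            b = m.branches[dt.segment_branch(node, nb)]
            weights.append(1.0 / (b.lam * b.r))
    total = sum(weights)
    return weights[nbrs.index(towards)] / total


def build_q(
    dt: DiscretisedTree,
    edge_order: Optional[Sequence[Tuple[str, str]]] = None,
    exact: bool = False,
) -> CoefficientMatrix:
    """Assemble the modified directed-edge adjacency matrix.

    With ``exact=True`` the entries are also returned as exact rationals
    (object array of Fractions); this requires equal diameters at every
    node, where p = 1/degree.
    """
    edges = list(edge_order) if edge_order is not None else dt.edges
    if edge_order is not None:
        if sorted(edges) != sorted(dt.edges):
            raise InvalidParameterError("edge_order must be a permutation of the edges")
    index = {e: i for i, e in enumerate(edges)}
    n = len(edges)
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    exact_mat = np.zeros((n, n), dtype=object) if exact else None
    if exact_mat is not None:
        exact_mat[:, :] = Fraction(0)
    for j, (u, v) in enumerate(edges):
        deg = dt.degree(v)
        terminal = dt.is_terminal(v)
        for w in dt.neighbors[v]:
            i = index[(v, w)]
            if w == u:  # reflection
                if terminal:
                    val = dt.m.terminal_sign(v)
                    fval = Fraction(int(val))
                else:
                    p = _dtree_node_factor(dt, v, u)
                    val = 2.0 * p - 1.0
                    fval = 2 * Fraction(1, deg) - 1 if exact else None
            else:       # pass-through
                p = _dtree_node_factor(dt, v, w)
                val = 2.0 * p
                fval = 2 * Fraction(1, deg) if exact else None
            rows.append(i)
            cols.append(j)
            vals.append(val)
            if exact_mat is not None:
                diams = {dt.diameter(v, nb) for nb in dt.neighbors[v]}
                if len(diams) != 1:
                    raise InvalidParameterError(
                        "exact rational Q requires equal diameters at every node"
                    )
                exact_mat[i, j] = fval
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return CoefficientMatrix(Q=Q, edges=edges, exact=exact_mat)


def class_lengths(k: int, x: float, y: float, dx: float) -> Tuple[float, float, float, float]:
    """Lengths of the four trip classes for a trip travelling k edges.

    A trip covering k edges spans k dx minus the untravelled stubs of its
    first and last edges.  With x dx the distance x -> s2 and y dx the
    distance g1 -> y:

        L1(k) = dx (k - 2 + x + y)     (start on s,  arrive along g)
        L2(k) = dx (k - 1 - x + y)     (start on s', arrive along g)
        L3(k) = dx (k - 1 + x - y)     (start on s,  arrive along g')
        L4(k) = dx (k - x - y)         (start on s', arrive along g')

    All satisfy L < k dx.  Each class only receives coefficient mass at edge
    counts of the correct parity (the corresponding entry of Q^(k-1) c_1
    vanishes otherwise), so the pairing with the coefficient recursion is
    exact; this bookkeeping is validated against exhaustive trip enumeration
    in the test suite.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise InvalidParameterError("x and y must be fractions in [0, 1]")
    return (
        dx * (k - 2.0 + x + y),
        dx * (k - 1.0 - x + y),
        dx * (k - 1.0 + x - y),
        dx * (k - x - y),
    )


def _orient_start_goal(
    dt: DiscretisedTree, x: PointOnBranch, y: PointOnBranch
) -> Tuple[Tuple[str, str], float, Tuple[str, str], float]:
    """Orient s and g so the shortest trip runs x -> s2 -> ... -> g1 -> y.

    Returns (s, xfrac, g, yfrac) with xfrac dx the distance x -> s2 and
    yfrac dx the distance g1 -> y.
    """
    (su, sv), fx = dt.locate(x)      # proximal -> distal along x's branch
    (gu, gv), fy = dt.locate(y)
    if (su, sv) == (gu, gv) or (su, sv) == (gv, gu):
        raise InvalidParameterError("x and y share an edge; re-discretise first")
    # choose s2: the endpoint of x's segment on the path to y's segment
    seen = {su}
    stack = [su]
    while stack:
        cur = stack.pop()
        for nb in dt.neighbors[cur]:
            if {cur, nb} == {su, sv} or nb in seen:
                continue
            seen.add(nb)
            stack.append(nb)
    towards_u = gu in seen and gv in seen
    if towards_u:
        s = (sv, su)
        xfrac = fx
    else:
        s = (su, sv)
        xfrac = 1.0 - fx
    seen = {gu}
    stack = [gu]
    while stack:
        cur = stack.pop()
        for nb in dt.neighbors[cur]:
            if {cur, nb} == {gu, gv} or nb in seen:
                continue
            seen.add(nb)
            stack.append(nb)
    from_u = s[1] in seen or s[0] in seen
    if from_u:
        g = (gu, gv)
        yfrac = fy
    else:
        g = (gv, gu)
        yfrac = 1.0 - fy
    return s, xfrac, g, yfrac


def matrix_greens(
    dt: DiscretisedTree,
    x: PointOnBranch,
    y: PointOnBranch,
    t: np.ndarray,
    kmax: int,
    coeff: Optional[CoefficientMatrix] = None,
) -> GreensSeries:
    """Green's function by iterated sparse products c_{k+1} = Q c_k.

    When x and y land on the same edge the tree is re-discretised locally so
    that they occupy different segments.
    """
    if kmax < 1:
        raise InvalidParameterError("kmax must be >= 1")
    t = np.asarray(t, dtype=float)
    m = dt.m
    x = nudge_off_node(m, x)
    y = nudge_off_node(m, y)
    try:
        s, xfrac, g, yfrac = _orient_start_goal(dt, x, y)
    except InvalidParameterError:
        if x.branch == y.branch and x.fraction != y.fraction:
            # refine the whole tree (one common dx is required) until x and
            # y land on different segments
            factor = 2
            while True:
                cand = discretise(m, dt.dx / factor)
                (e1, _), (e2, _) = cand.locate(x), cand.locate(y)
                if e1 != e2:
                    dt, coeff = cand, None
                    break
                factor *= 2
                if factor > 4096:
                    raise
            s, xfrac, g, yfrac = _orient_start_goal(dt, x, y)
        else:
            raise
    if coeff is None:
        coeff = build_q(dt)
    Q = coeff.Q
    idx = {e: i for i, e in enumerate(coeff.edges)}
    cs = np.zeros(len(coeff.edges))
    cs[idx[s]] = 1.0
    csp = np.zeros(len(coeff.edges))
    csp[idx[(s[1], s[0])]] = 1.0
    ig, igp = idx[g], idx[(g[1], g[0])]
    bj = m.branches[y.branch]
    dx_eff = dt.dx
    # diffusion-range advisory
    span = 6.0 * math.sqrt(4.0 * float(t[-1]) / m.tau)
    if kmax * dx_eff < span:
        warnings.warn(
            f"kmax={kmax} covers {kmax * dx_eff:.3g} electrotonic lengths, "
            f"less than the diffusion range {span:.3g}; increase kmax"
        )
    values = np.zeros_like(t)
    for k in range(1, kmax + 1):
        L1, L2, L3, L4 = class_lengths(k, xfrac, yfrac, dx_eff)
        for c, iy, L in ((cs, ig, L1), (csp, ig, L2), (cs, igp, L3), (csp, igp, L4)):
            A = c[iy]
            if A != 0.0:
                values += A * ginf(L, t, bj.D, bj.tau)
        if k < kmax:
            cs = Q @ cs
            csp = Q @ csp
    values *= source_prefactor(m, y.branch)
    return GreensSeries(
        t, values, x, y,
        {"method": "matrix", "kmax": kmax, "dx": dx_eff,
         "distortion": dt.max_distortion},
    )


def matrix_greens_all(
    dt: DiscretisedTree,
    x: PointOnBranch,
    t: np.ndarray,
    kmax: int,
    y_fraction: float = 0.5,
    coeff: Optional[CoefficientMatrix] = None,
) -> Dict[Tuple[str, str], GreensSeries]:
    """Green's functions from x to a point on every segment in one sweep.

    A single iteration of the two coefficient vectors serves every goal edge
    simultaneously; ``y_fraction`` places y at the same relative position on
    every segment (measured from the endpoint nearer x).  The segment
    carrying x itself is skipped.
    """
    t = np.asarray(t, dtype=float)
    m = dt.m
    x = nudge_off_node(m, x)
    if coeff is None:
        coeff = build_q(dt)
    Q = coeff.Q
    idx = {e: i for i, e in enumerate(coeff.edges)}
    (su, sv), fx = dt.locate(x)
    # component of each node when x's segment is removed: True = su side
    side: Dict[str, bool] = {}
    for start, flag in ((su, True), (sv, False)):
        side[start] = flag
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in dt.neighbors[cur]:
                if {cur, nb} == {su, sv} or nb in side:
                    continue
                side[nb] = flag
                stack.append(nb)
    # start vectors: cA starts on (sv, su) (towards the su side), cB on (su, sv)
    cA = np.zeros(len(coeff.edges))
    cA[idx[(sv, su)]] = 1.0
    cB = np.zeros(len(coeff.edges))
    cB[idx[(su, sv)]] = 1.0
    xfrac = {True: fx, False: 1.0 - fx}

    def x_side_endpoint(key: Tuple[str, str]) -> str:
        """Endpoint of a segment whose component (segment removed) holds x."""
        a, b = key
        seen = {a}
        stack = [a]
        while stack:
            cur = stack.pop()
            if cur in (su, sv):
                return a
            for nb in dt.neighbors[cur]:
                if {cur, nb} == set(key) or nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
        return b

    goals: List[Tuple[Tuple[str, str], bool, Tuple[str, str]]] = []
    for key in sorted({tuple(sorted(e)) for e in coeff.edges}):
        if key == tuple(sorted((su, sv))):
            continue
        g1 = x_side_endpoint(key)
        g = (g1, key[1] if g1 == key[0] else key[0])
        goals.append((key, side[g1], g))
    gidx = np.array([idx[g] for _, _, g in goals])
    gpidx = np.array([idx[(g[1], g[0])] for _, _, g in goals])
    sides = np.array([s for _, s, _ in goals])
    Dg = np.array([m.branches[dt.of_branch[key]].D for key, _, _ in goals])
    values = np.zeros((len(goals), len(t)))
    for k in range(1, kmax + 1):
        for is_su in (True, False):
            mask = sides == is_su
            if not mask.any():
                continue
            rows = np.where(mask)[0]
            Ls = class_lengths(k, xfrac[is_su], y_fraction, dt.dx)
            for c, ei, L in zip(
                (cA, cB, cA, cB) if is_su else (cB, cA, cB, cA),
                (gidx[mask], gidx[mask], gpidx[mask], gpidx[mask]),
                Ls,
            ):
                amps = c[ei]
                nz = amps != 0.0
                if nz.any():
                    r = rows[nz]
                    base = ginf(L, t, 1.0, m.tau)  # 1/sqrt(D) factored out
                    values[r] += (amps[nz] / np.sqrt(Dg[r]))[:, None] * base
        if k < kmax:
            cA = Q @ cA
            cB = Q @ cB
    out: Dict[Tuple[str, str], GreensSeries] = {}
    for (key, _, g), vals in zip(goals, values):
        bid = dt.of_branch[key]
        chain = dt.branch_chain(bid)
        seg_i = next(
            i for i, (u, v) in enumerate(zip(chain, chain[1:]))
            if tuple(sorted((u, v))) == key
        )
        offset = y_fraction if g[0] == chain[seg_i] else 1.0 - y_fraction
        yp = PointOnBranch(bid, (seg_i + offset) / dt.n_per_branch[bid])
        out[key] = GreensSeries(
            t, vals * source_prefactor(m, bid), x, yp,
            {"method": "matrix-all", "kmax": kmax, "dx": dt.dx},
        )
    return out
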