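"""Branched-cable morphologies: data model, electrotonic parameters, generators.

A morphology is a connected, acyclic graph of uniform cylinders ("branches")
joined at nodes.  Each branch carries a physical length ``L`` and diameter
``a`` together with the electrotonic quantities derived from the membrane
parameters:

* space constant      ``lambda = sqrt(a R / (4 Ra))``
* time constant       ``tau = R C``  (must be uniform over the whole tree)
* diffusion constant  ``D = lambda**2 / tau``
* axial resistance    ``r = 4 Ra / (pi a**2)``  (per unit length)

Two unit systems are supported.  In the default *physical* system lengths are
in micrometres, times in milliseconds, ``C`` in uF cm^-2, ``R`` in Ohm cm^2
and ``Ra`` in Ohm cm; the derivations above then carry the appropriate
conversion factors.  In the *dimensionless* system the formulas are applied
verbatim, which is convenient for non-dimensionalised model trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "InvalidParameterError",
    "CableParameters",
    "Branch",
    "Node",
    "Morphology",
    "PointOnBranch",
    "make_binary_tree",
    "make_y_tree",
    "make_double_junction_tree",
    "make_random_binary_tree",
    "make_cable",
    "parse_point",
]


class InvalidParameterError(ValueError):
    """Raised for non-positive or inconsistent cable parameters."""


_REL_TOL = 1e-9


@dataclass(frozen=True)
class CableParameters:
    """Specific membrane/cytoplasm parameters shared by the whole tree.

    Parameters
    ----------
    C : specific membrane capacitance (uF cm^-2, or raw in dimensionless mode)
    R : specific membrane resistance (Ohm cm^2)
    Ra : specific cytoplasmic resistivity (Ohm cm)
    dimensionless : if True, no unit conversions are applied
    boundary : default terminal boundary condition, "closed" or "open"
    overrides : optional per-branch overrides, branch id -> dict with any of
        the keys ``R``, ``Ra``, ``C``.  The membrane time constant tau = R C
        must stay uniform across branches; an override of ``R`` therefore
        requires a compensating ``C``.
    """

    C: float = 1.0
    R: float = 3000.0
    Ra: float = 100.0
    dimensionless: bool = False
    boundary: str = "closed"
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.R <= 0 or self.Ra <= 0:
            raise InvalidParameterError("C, R and Ra must be strictly positive")
        if self.boundary not in ("closed", "open"):
            raise InvalidParameterError(f"unknown boundary {self.boundary!r}")
        tau0 = self.tau
        for bid, ov in self.overrides.items():
            R = ov.get("R", self.R)
            C = ov.get("C", self.C)
            if R <= 0 or C <= 0 or ov.get("Ra", self.Ra) <= 0:
                raise InvalidParameterError(f"override for branch {bid!r} not positive")
            tau = R * C * (1e-3 if not self.dimensionless else 1.0)
            if abs(tau - tau0) > _REL_TOL * tau0:
                raise InvalidParameterError(
                    f"override for branch {bid!r} changes tau ({tau} != {tau0}); "
                    "the time-domain series requires a uniform time constant"
                )

    @property
    def tau(self) -> float:
        """Membrane time constant (ms in physical mode)."""
        scale = 1.0 if self.dimensionless else 1e-3
        return self.R * self.C * scale

    def membrane(self, branch_id: Optional[str] = None) -> Tuple[float, float, float]:
        """(C, R, Ra) effective for a branch, honouring overrides."""
        ov = self.overrides.get(branch_id, {}) if branch_id is not None else {}
        return ov.get("C", self.C), ov.get("R", self.R), ov.get("Ra", self.Ra)

    @property
    def uniform(self) -> bool:
        """True when no per-branch overrides are present."""
        return not self.overrides

    @classmethod
    def from_diffusion(
        cls,
        D: float,
        tau: float,
        a: float,
        C: float = 1.0,
        dimensionless: bool = False,
        boundary: str = "closed",
    ) -> "CableParameters":
        """Build parameters from a target diffusion coefficient and time
        constant for a reference diameter ``a``.

        Solves lambda**2 = D tau, R = tau / C and Ra = a R / (4 lambda**2)
        (with unit conversions in physical mode), so that branches of
        diameter ``a`` have exactly the requested ``D`` and ``tau``.
        """
        if D <= 0 or tau <= 0 or a <= 0 or C <= 0:
            raise InvalidParameterError("D, tau, a and C must be strictly positive")
        lam2 = D * tau
        if dimensionless:
            R = tau / C
            Ra = a * R / (4.0 * lam2)
        else:
            R = tau * 1e3 / C          # Ohm cm^2 from ms and uF cm^-2
            Ra = 1e4 * a * R / (4.0 * lam2)   # Ohm cm; a um, lam2 um^2
        return cls(C=C, R=R, Ra=Ra, dimensionless=dimensionless, boundary=boundary)


def derive_electrotonic(
    L: float, a: float, params: CableParameters, branch_id: Optional[str] = None
) -> Tuple[float, float, float, float]:
    """Return (lambda, tau, D, r) for a cylinder of length L and diameter a.

    lambda in um, tau in ms, D in um^2 ms^-1 and r in Ohm cm^-1 in physical
    mode; raw formula values in dimensionless mode.
    """
    if L <= 0 or a <= 0:
        raise InvalidParameterError("branch length and diameter must be positive")
    C, R, Ra = params.membrane(branch_id)
    if params.dimensionless:
        lam = math.sqrt(a * R / (4.0 * Ra))
        tau = R * C
        r = 4.0 * Ra / (math.pi * a * a)
    else:
        # a [um] -> cm inside the sqrt, result back to um
        lam = 1e2 * math.sqrt(a * R / (4.0 * Ra))
        tau = R * C * 1e-3
        r = 4.0 * Ra / (math.pi * (a * 1e-4) ** 2)
    D = lam * lam / tau
    return lam, tau, D, r


@dataclass(frozen=True)
class Branch:
    """A uniform cylinder between two nodes."""

    id: str
    proximal: str
    distal: str
    L: float
    a: float
    lam: float
    D: float
    tau: float
    r: float

    @property
    def el(self) -> float:
        """Electrotonic length L / lambda."""
        return self.L / self.lam


@dataclass(frozen=True)
class Node:
    id: str
    kind: str = "internal"          # "internal" | "terminal"
    boundary: Optional[str] = None  # "closed" | "open" for terminals


@dataclass(frozen=True)
class PointOnBranch:
    """A location on a branch, as a fraction in [0, 1] from the proximal end."""

    branch: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidParameterError(
                f"fraction {self.fraction} outside [0, 1] on branch {self.branch!r}"
            )

    def __str__(self) -> str:
        return f"{self.branch}:{self.fraction:g}"


def parse_point(text: str) -> PointOnBranch:
    """Parse a "branchId:fraction" string."""
    branch, _, frac = text.rpartition(":")
    if not branch:
        raise InvalidParameterError(f"cannot parse point {text!r}; expected 'branch:fraction'")
    return PointOnBranch(branch, float(frac))


class Morphology:
    """A tree of branches with derived electrotonic parameters.

    Branch and node ids are strings.  The root node orients the tree (it is
    the soma-side reference); ``proximal`` endpoints face the root.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        branches: Iterable[Branch],
        params: CableParameters,
        root: str,
    ) -> None:
        self.nodes: Dict[str, Node] = {n.id: n for n in nodes}
        self.branches: Dict[str, Branch] = {b.id: b for b in branches}
        self.params = params
        self.root = root
        self._adj: Dict[str, List[Tuple[str, str]]] = {nid: [] for nid in self.nodes}
        for b in self.branches.values():
            self._adj[b.proximal].append((b.id, b.distal))
            self._adj[b.distal].append((b.id, b.proximal))
        for lst in self._adj.values():
            lst.sort()
        self._pcache: Dict[Tuple[str, str], float] = {}
        self._coeff_cache: Dict[Tuple, float] = {}

    # -- basic queries ---------------------------------------------------

    def neighbors(self, node_id: str) -> List[Tuple[str, str]]:
        """List of (branch id, other node id) incident to a node."""
        return self._adj[node_id]

    def degree(self, node_id: str) -> int:
        return len(self._adj[node_id])

    def incident_branches(self, node_id: str) -> List[str]:
        return [b for b, _ in self._adj[node_id]]

    def endpoints(self, branch_id: str) -> Tuple[str, str]:
        b = self.branches[branch_id]
        return b.proximal, b.distal

    def other_end(self, branch_id: str, node_id: str) -> str:
        b = self.branches[branch_id]
        if node_id == b.proximal:
            return b.distal
        if node_id == b.distal:
            return b.proximal
        raise KeyError(f"node {node_id!r} is not an endpoint of branch {branch_id!r}")

    def branch_between(self, u: str, v: str) -> str:
        for bid, other in self._adj[u]:
            if other == v:
                return bid
        raise KeyError(f"no branch between {u!r} and {v!r}")

    def is_terminal(self, node_id: str) -> bool:
        return self.nodes[node_id].kind == "terminal"

    def terminal_sign(self, node_id: str) -> float:
        node = self.nodes[node_id]
        boundary = node.boundary or self.params.boundary
        return 1.0 if boundary == "closed" else -1.0

    def el(self, branch_id: str) -> float:
        return self.branches[branch_id].el

    def point(self, branch_id: str, fraction: float) -> PointOnBranch:
        if branch_id not in self.branches:
            raise KeyError(f"unknown branch {branch_id!r}")
        return PointOnBranch(branch_id, fraction)

    @property
    def tau(self) -> float:
        return self.params.tau

    # -- tree walks ------------------------------------------------------

    def node_path(self, u: str, v: str) -> List[str]:
        """Unique node path from u to v (inclusive)."""
        if u == v:
            return [u]
        parent: Dict[str, Optional[str]] = {u: None}
        stack = [u]
        while stack:
            cur = stack.pop()
            if cur == v:
                break
            for _, nxt in self._adj[cur]:
                if nxt not in parent:
                    parent[nxt] = cur
                    stack.append(nxt)
        if v not in parent:
            raise KeyError(f"no path from {u!r} to {v!r}")
        path = [v]
        while path[-1] != u:
            path.append(parent[path[-1]])  # type: ignore[arg-type]
        path.reverse()
        return path

    def node_distances(self, source: str) -> Dict[str, float]:
        """Electrotonic distance from ``source`` node to every node."""
        dist = {source: 0.0}
        stack = [source]
        while stack:
            cur = stack.pop()
            for bid, nxt in self._adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + self.el(bid)
                    stack.append(nxt)
        return dist

    def distance_to_point(self, node_id: str, p: PointOnBranch) -> float:
        """Electrotonic distance from a node to an interior point."""
        prox, dist_ = self.endpoints(p.branch)
        elb = self.el(p.branch)
        d = self.node_distances(node_id)
        via_prox = d[prox] + p.fraction * elb
        via_dist = d[dist_] + (1.0 - p.fraction) * elb
        return min(via_prox, via_dist)

    def point_segments(self, p: PointOnBranch) -> Dict[str, float]:
        """Electrotonic length of the partial segment from p to each endpoint."""
        prox, dist_ = self.endpoints(p.branch)
        elb = self.el(p.branch)
        return {prox: p.fraction * elb, dist_: (1.0 - p.fraction) * elb}

    # -- validation ------------------------------------------------------

    def validate(self) -> List[str]:
        """Return a list of invariant violations (empty iff valid)."""
        report: List[str] = []
        nn, nb = len(self.nodes), len(self.branches)
        if nb != nn - 1:
            report.append(f"tree invariant violated: {nb} branches, {nn} nodes")
        for b in self.branches.values():
            if b.proximal not in self.nodes or b.distal not in self.nodes:
                report.append(f"branch {b.id!r} references a missing node")
            if b.L <= 0:
                report.append(f"branch {b.id!r} has non-positive length {b.L}")
            if b.a <= 0:
                report.append(f"branch {b.id!r} has non-positive diameter {b.a}")
        if self.root not in self.nodes:
            report.append(f"root node {self.root!r} missing")
            return report
        # connectivity / acyclicity via DFS
        seen = {self.root}
        stack = [(self.root, None)]
        cyclic = False
        while stack:
            cur, via = stack.pop()
            for bid, nxt in self._adj[cur]:
                if bid == via:
                    continue
                if nxt in seen:
                    cyclic = True
                    continue
                seen.add(nxt)
                stack.append((nxt, bid))
        if cyclic:
            report.append("graph contains a cycle")
        if len(seen) != nn:
            report.append(f"graph not connected: {nn - len(seen)} unreachable node(s)")
        for node in self.nodes.values():
            deg = self.degree(node.id)
            if node.kind == "terminal" and deg != 1:
                report.append(f"terminal {node.id!r} has degree {deg}")
            if node.kind == "internal" and deg < 2:
                report.append(f"internal node {node.id!r} has degree {deg}")
        taus = {b.id: b.tau for b in self.branches.values()}
        if taus:
            t0 = next(iter(taus.values()))
            for bid, t in taus.items():
                if abs(t - t0) > _REL_TOL * abs(t0):
                    report.append(
                        f"branch {bid!r} has tau {t} != {t0}: non-uniform time constant"
                    )
                    break
        return report


# -- construction helpers -----------------------------------------------


def _build(
    edges: Sequence[Tuple[str, str, str, float, float]],
    params: CableParameters,
    root: str,
    terminals_boundary: Optional[Mapping[str, str]] = None,
) -> Morphology:
    """Assemble a Morphology from (branch id, proximal, distal, L, a) tuples."""
    node_ids = {root}
    for _, u, v, _, _ in edges:
        node_ids.add(u)
        node_ids.add(v)
    degree: Dict[str, int] = {nid: 0 for nid in node_ids}
    for _, u, v, _, _ in edges:
        degree[u] += 1
        degree[v] += 1
    terminals_boundary = terminals_boundary or {}
    nodes = [
        Node(
            nid,
            kind="terminal" if degree[nid] == 1 else "internal",
            boundary=(
                terminals_boundary.get(nid, params.boundary) if degree[nid] == 1 else None
            ),
        )
        for nid in sorted(node_ids)
    ]
    branches = []
    for bid, u, v, L, a in edges:
        lam, tau, D, r = derive_electrotonic(L, a, params, bid)
        branches.append(Branch(bid, u, v, L, a, lam, D, tau, r))
    return Morphology(nodes, branches, params, root)


def make_binary_tree(
    depth: int, L: float, a: float, params: CableParameters
) -> Morphology:
    """Full binary tree: a root branch followed by depth-1 bifurcation levels.

    A tree of depth ``d`` has ``2**d`` nodes and ``2**d - 1`` branches, all of
    length ``L`` and diameter ``a``.  Node ids follow the heap convention:
    the root node is "1", the root branch ends at "2" and node ``m`` has
    children ``2m`` and ``2m+1``.  Branch ids equal their distal node id.
    All terminals take the default boundary condition of ``params``.
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    edges: List[Tuple[str, str, str, float, float]] = [("2", "1", "2", L, a)]
    prev = [2]
    for _ in range(depth - 1):
        nxt: List[int] = []
        for m in prev:
            for c in (2 * m, 2 * m + 1):
                edges.append((str(c), str(m), str(c), L, a))
                nxt.append(c)
        prev = nxt
    return _build(edges, params, root="1")


def make_y_tree(dx: float, a: float, params: CableParameters) -> Morphology:
    """Three branches of equal length ``dx`` joined at a central node B.

    Terminals A, C, D; branches "AB", "BC", "BD"; root A.
    """
    if dx <= 0:
        raise InvalidParameterError("dx must be positive")
    edges = [
        ("AB", "A", "B", dx, a),
        ("BC", "B", "C", dx, a),
        ("BD", "B", "D", dx, a),
    ]
    return _build(edges, params, root="A")


def make_double_junction_tree(L: float, a: float, params: CableParameters) -> Morphology:
    """A five-branch structure with two junctions, used as a test geometry.

    Terminal A joins junction B; B carries a side branch to terminal E and a
    trunk to junction C, which splits to terminals F and G.  Measurement and
    injection points are typically placed on "AB" and "BC".
    """
    edges = [
        ("AB", "A", "B", L, a),
        ("BC", "B", "C", L, a),
        ("BE", "B", "E", L, a),
        ("CF", "C", "F", L, a),
        ("CG", "C", "G", L, a),
    ]
    return _build(edges, params, root="A")


def make_cable(L: float, a: float, params: CableParameters, n_segments: int = 1) -> Morphology:
    """A single unbranched cable, optionally split into collinear segments.

    Node ids "0".."n"; branch ids "seg1".."segn"; root "0".
    """
    if n_segments < 1:
        raise InvalidParameterError("n_segments must be >= 1")
    seg = L / n_segments
    edges = [
        (f"seg{i + 1}", str(i), str(i + 1), seg, a) for i in range(n_segments)
    ]
    return _build(edges, params, root="0")


def make_random_binary_tree(
    n_branches: int,
    seed: int,
    params: Optional[CableParameters] = None,
    L_range: Tuple[float, float] = (30.0, 120.0),
    a_range: Tuple[float, float] = (0.6, 1.6),
) -> Morphology:
    """Random tree with node degree <= 3, random lengths and diameters.

    Grown by repeatedly bifurcating a random terminal; deterministic for a
    given seed.
    """
    import random

    if n_branches < 1:
        raise InvalidParameterError("n_branches must be >= 1")
    rng = random.Random(seed)
    params = params or CableParameters()
    counter = [1]

    def draw() -> Tuple[float, float]:
        return rng.uniform(*L_range), rng.uniform(*a_range)

    edges: List[Tuple[str, str, str, float, float]] = []
    L0, a0 = draw()
    edges.append(("b1", "n0", "n1", L0, a0))
    tips = ["n1"]
    counter = [1]
    while len(edges) < n_branches:
        tip = tips.pop(rng.randrange(len(tips)))
        take = min(2, n_branches - len(edges))
        for _ in range(take):
            counter[0] += 1
            nid = f"n{counter[0]}"
            L, a = draw()
            edges.append((f"b{len(edges) + 1}", tip, nid, L, a))
            tips.append(nid)
        if not tips:
            break
    return _build(edges, params, root="n0")
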