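"""Deterministic trip generators.

Three generators with one contract -- every x->y trip produced exactly once:

* ``four_classes_seed`` builds the four shortest trips (one per class,
  distinguished by the departure direction from x and the arrival direction
  at y); these seed the grammar generator.
* ``enumerate_grammar`` grows trips from the seeds by inserting two-node
  "excursions", restricted to a leftmost derivation and to excursions that
  follow a per-branch direction assignment (every branch directed away from
  x; the branch carrying x directed away from y).  The two restrictions make
  the generation unambiguous: no trip is derived twice.
* ``enumerate_length_priority`` emits trips in non-decreasing electrotonic
  length via a best-first search over walk prefixes with a priority queue
  keyed by accumulated length (ties broken lexicographically on the node
  sequence), the shortest-trips ordering of Eppstein-style k-shortest-walk
  enumeration.

``brute_force_walks`` is the exhaustive oracle used to validate both.
"""

from __future__ import annotations

import heapq
import warnings
from typing import Dict, Iterator, List, Optional, Tuple

from .core import Trip, make_trip
from .morphology import InvalidParameterError, Morphology, PointOnBranch

__all__ = [
    "four_classes_seed",
    "branch_directions",
    "enumerate_grammar",
    "enumerate_length_priority",
    "brute_force_walks",
    "nudge_off_node",
]

_NUDGE = 1e-9


def _require_tree(m: Morphology) -> None:
    """Trip enumeration needs an acyclic structure: "away from a point" is
    not definable on a graph with cycles."""
    if len(m.branches) != len(m.nodes) - 1:
        raise InvalidParameterError(
            "trip enumeration requires an acyclic (tree) morphology"
        )


def nudge_off_node(m: Morphology, p: PointOnBranch) -> PointOnBranch:
    """Move a point sitting exactly on a node slightly into the branch.

    The class definitions presuppose interior points; a warning is issued
    when a nudge is applied.
    """
    if p.fraction == 0.0 or p.fraction == 1.0:
        frac = _NUDGE if p.fraction == 0.0 else 1.0 - _NUDGE
        warnings.warn(
            f"point {p} lies on a node; nudged to fraction {frac:g}"
        )
        return PointOnBranch(p.branch, frac)
    return p


def _towards(m: Morphology, x: PointOnBranch, y: PointOnBranch) -> Tuple[str, str]:
    """Endpoints (near, far) of x's branch relative to the route to y.

    ``near`` is the endpoint of x's branch through which the direct x->y trip
    leaves (for x, y on the same branch: the endpoint on y's side of x).
    """
    u, v = m.endpoints(x.branch)
    if x.branch == y.branch:
        return (v, u) if y.fraction >= x.fraction else (u, v)
    # removing x's branch splits the tree; the near endpoint is the one in
    # y's component
    seen = {u}
    stack = [u]
    while stack:
        cur = stack.pop()
        for bid, nxt in m.neighbors(cur):
            if bid == x.branch or nxt in seen:
                continue
            seen.add(nxt)
            stack.append(nxt)
    yu, yv = m.endpoints(y.branch)
    return (u, v) if yu in seen else (v, u)


def four_classes_seed(
    m: Morphology, x: PointOnBranch, y: PointOnBranch
) -> Tuple[Trip, Trip, Trip, Trip]:
    """The four shortest trips, one per class.

    Class 1 is the most direct trip; Class 2 leaves x backwards; Class 3
    overshoots y and reflects; Class 4 does both.
    """
    x = nudge_off_node(m, x)
    y = nudge_off_node(m, y)
    if x == y:
        raise InvalidParameterError("four classes need x != y")
    if x.branch == y.branch:
        u, v = m.endpoints(x.branch)
        if y.fraction >= x.fraction:
            behind, beyond = u, v
        else:
            behind, beyond = v, u
        seqs = [(), (behind,), (beyond,), (behind, beyond)]
    else:
        near_x, far_x = _towards(m, x, y)
        near_y, far_y = _towards(m, y, x)
        direct = m.node_path(near_x, near_y)
        seqs = [
            tuple(direct),
            (far_x, *direct),
            (*direct, far_y),
            (far_x, *direct, far_y),
        ]
    return tuple(make_trip(m, s, x, y) for s in seqs)  # type: ignore[return-value]


def branch_directions(
    m: Morphology, x: PointOnBranch, y: PointOnBranch
) -> Dict[str, Tuple[str, str]]:
    """Direction (tail, head) per branch for excursion filtering.

    Every branch is directed away from x; the branch carrying x is directed
    away from y.  An excursion at node n towards neighbour w is allowed only
    when the branch between them is directed n -> w.
    """
    dirs: Dict[str, Tuple[str, str]] = {}
    near_x, far_x = _towards(m, x, y)
    # orient x's own branch away from y
    dirs[x.branch] = (near_x, far_x)
    # every other branch away from x: traverse outward from both endpoints
    stack = [near_x, far_x]
    while stack:
        cur = stack.pop()
        for bid, nxt in m.neighbors(cur):
            if bid == x.branch or bid in dirs:
                continue
            dirs[bid] = (cur, nxt)
            stack.append(nxt)
    return dirs


def enumerate_grammar(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    max_nodes: Optional[int] = None,
    max_trips: Optional[int] = None,
) -> Iterator[Trip]:
    """Generate every x->y trip exactly once, in node-count order.

    Trips are derived from the four class seeds by excursion insertion under
    the leftmost-derivation and branch-direction restrictions.  Within a
    node count, trips are emitted in lexicographic order of their node
    sequences.  For x and y on a common branch the class seeds do not span
    all departure/arrival combinations reachable without excursions, so the
    generator falls back to exhaustive prefix expansion (still duplicate
    free, still ordered).
    """
    _require_tree(m)
    x = nudge_off_node(m, x)
    y = nudge_off_node(m, y)
    if max_nodes is None and max_trips is None:
        raise InvalidParameterError("need a max_nodes or max_trips budget")
    if x.branch == y.branch:
        yield from brute_force_walks(m, x, y, max_nodes, max_trips, _checked=False)
        return
    dirs = branch_directions(m, x, y)
    seeds = four_classes_seed(m, x, y)
    # heap of (node count, sequence, marker); marker = first index at or
    # after which excursions may be inserted (leftmost derivation)
    heap: List[Tuple[int, Tuple[str, ...], int]] = []
    for trip in seeds:
        heapq.heappush(heap, (len(trip.nodes), trip.nodes, 0))
    count = 0
    while heap:
        n, seq, marker = heapq.heappop(heap)
        if max_nodes is not None and n > max_nodes:
            break
        yield make_trip(m, seq, x, y)
        count += 1
        if max_trips is not None and count >= max_trips:
            break
        if max_nodes is not None and n + 2 > max_nodes:
            continue
        for p in range(marker, n):
            node = seq[p]
            for bid, w in m.neighbors(node):
                if dirs[bid] != (node, w):
                    continue
                new_seq = seq[: p + 1] + (w, node) + seq[p + 1 :]
                heapq.heappush(heap, (n + 2, new_seq, p + 1))


def _start_states(
    m: Morphology, x: PointOnBranch
) -> List[Tuple[float, Tuple[str, ...]]]:
    segs = m.point_segments(x)
    return [(seg, (node,)) for node, seg in sorted(segs.items())]


def enumerate_length_priority(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    n_trips: Optional[int] = None,
    max_length: Optional[float] = None,
) -> Iterator[Trip]:
    """Emit trips in non-decreasing electrotonic length L_trip.

    Best-first search over walk prefixes: the priority queue is keyed by the
    accumulated length (the exact final length for completed trips), with
    lexicographic node-sequence tie-breaking.  Stops after ``n_trips`` trips
    or when lengths exceed ``max_length``, whichever comes first.
    """
    _require_tree(m)
    x = nudge_off_node(m, x)
    y = nudge_off_node(m, y)
    if n_trips is None and max_length is None:
        raise InvalidParameterError("need an n_trips or max_length budget")
    if n_trips is not None and n_trips < 1:
        raise InvalidParameterError("n_trips must be >= 1")
    y_ends = set(m.endpoints(y.branch))
    y_segs = m.point_segments(y)
    # heap entries: (length, kind, sequence); kind 0 = completed trip,
    # kind 1 = extendable walk prefix ending at sequence[-1]
    heap: List[Tuple[float, int, Tuple[str, ...]]] = []
    if x.branch == y.branch:
        heapq.heappush(
            heap, (abs(x.fraction - y.fraction) * m.el(x.branch), 0, ())
        )
    for g, seq in _start_states(m, x):
        heapq.heappush(heap, (g, 1, seq))
    emitted = 0
    while heap:
        length, kind, seq = heapq.heappop(heap)
        if max_length is not None and length > max_length:
            break
        if kind == 0:
            yield make_trip(m, seq, x, y)
            emitted += 1
            if n_trips is not None and emitted >= n_trips:
                break
            continue
        node = seq[-1]
        if node in y_ends:
            heapq.heappush(heap, (length + y_segs[node], 0, seq))
        for bid, nxt in m.neighbors(node):
            heapq.heappush(heap, (length + m.el(bid), 1, seq + (nxt,)))


def brute_force_walks(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    max_nodes: Optional[int] = None,
    max_trips: Optional[int] = None,
    max_states: int = 2_000_000,
    _checked: bool = True,
) -> Iterator[Trip]:
    """Exhaustively enumerate all trips with up to ``max_nodes`` node visits.

    Breadth-first expansion of walk prefixes; intended as a small-scale
    oracle (the walk count grows like 3^k on degree-3 trees).  Emits trips
    in (node count, lexicographic) order, each exactly once.
    """
    if _checked:
        x = nudge_off_node(m, x)
        y = nudge_off_node(m, y)
    if max_nodes is None and max_trips is None:
        raise InvalidParameterError("need a max_nodes or max_trips budget")
    y_ends = set(m.endpoints(y.branch))
    frontier: List[Tuple[str, ...]] = [()]
    states = 0
    emitted = 0
    n = 0
    while frontier:
        if max_nodes is not None and n > max_nodes:
            break
        for seq in frontier:
            complete = (
                seq[-1] in y_ends if seq else x.branch == y.branch
            )
            if complete:
                yield make_trip(m, seq, x, y)
                emitted += 1
                if max_trips is not None and emitted >= max_trips:
                    return
        nxt_frontier: List[Tuple[str, ...]] = []
        for seq in frontier:
            if seq:
                steps = [w for _, w in m.neighbors(seq[-1])]
            else:
                steps = list(m.endpoints(x.branch))
            for w in steps:
                nxt_frontier.append(seq + (w,))
                states += 1
                if states > max_states:
                    raise ResourceWarning(
                        "brute-force walk budget exceeded; reduce max_nodes"
                    )
        nxt_frontier.sort()
        frontier = nxt_frontier
        n += 1
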