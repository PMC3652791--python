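"""SWC reading and writing.

The reader accepts the standard 7-column SWC dialect (``id type x y z radius
parent``, whitespace separated, '#' comments) and collapses unbranched chains
of sample points into uniform cylinders.  Within a chain, every consecutive
pair of samples defines a frustum whose diameter is taken as the mean of the
two endpoint diameters and whose length is the 3D Euclidean distance; a
collapsed branch reports the summed length and the length-weighted mean
diameter of its frusta.  All type-1 (soma) samples collapse onto a single
root node: the soma is treated as a location, not a compartment.

The writer exists mainly to produce round-trippable fixtures: it embeds the
tree in the plane and emits one sample per node, choosing radii so that the
mean-diameter rule recovers each branch diameter exactly.
"""

from __future__ import annotations

import io
import math
from typing import Dict, List, Optional, TextIO, Tuple, Union

from .morphology import (
    Branch,
    CableParameters,
    Morphology,
    Node,
    derive_electrotonic,
)

__all__ = ["SwcFormatError", "read_swc", "write_swc"]


class SwcFormatError(ValueError):
    """Malformed SWC content; carries the offending line number when known."""

    def __init__(self, message: str, line: Optional[int] = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _open(source: Union[str, TextIO]) -> Tuple[TextIO, bool]:
    if isinstance(source, str):
        if "\n" in source:
            return io.StringIO(source), True
        return open(source, "r"), True
    return source, False


def read_swc(
    source: Union[str, TextIO],
    params: Optional[CableParameters] = None,
    split_on_radius_change: bool = False,
) -> Morphology:
    """Parse an SWC stream, file path or literal string into a Morphology.

    Parameters
    ----------
    params : membrane parameters used to derive electrotonic quantities
        (defaults to ``CableParameters()``).
    split_on_radius_change : when True, a change of sample radius inside an
        unbranched chain starts a new branch, preserving the diameter jumps
        that reconstructions encode at sample points.  By default chains are
        split only at topological branch points.
    """
    params = params or CableParameters()
    stream, close = _open(source)
    try:
        samples: Dict[int, Tuple[int, float, float, float, float, int]] = {}
        order: List[int] = []
        lineno_of: Dict[int, int] = {}
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcFormatError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                sid = int(parts[0])
                stype = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcFormatError(str(exc), lineno) from None
            if sid in samples:
                raise SwcFormatError(f"duplicate sample id {sid}", lineno)
            if parent == sid:
                raise SwcFormatError(f"sample {sid} is its own parent", lineno)
            samples[sid] = (stype, x, y, z, radius, parent)
            order.append(sid)
            lineno_of[sid] = lineno
    finally:
        if close:
            stream.close()

    if not samples:
        raise SwcFormatError("no samples found")

    roots = [sid for sid in order if samples[sid][5] == -1]
    if not roots:
        raise SwcFormatError("no root sample (parent -1)")
    for sid in order:
        parent = samples[sid][5]
        if parent != -1 and parent not in samples:
            raise SwcFormatError(f"sample {sid} has unknown parent {parent}", lineno_of[sid])

    # cycle detection over parent links
    state: Dict[int, int] = {}
    for sid in order:
        chain = []
        cur: int = sid
        while cur != -1 and state.get(cur, 0) == 0:
            state[cur] = 1
            chain.append(cur)
            cur = samples[cur][5]
        if cur != -1 and state[cur] == 1:
            raise SwcFormatError(f"cycle in parent links at sample {cur}", lineno_of[cur])
        for c in chain:
            state[c] = 2

    # collapse all soma samples (type 1) to a single root node
    soma_ids = {sid for sid in order if samples[sid][0] == 1}
    non_soma_roots = [sid for sid in roots if sid not in soma_ids]
    if soma_ids:
        soma_roots = [sid for sid in roots if sid in soma_ids]
        if not soma_roots:
            raise SwcFormatError("soma samples present but none is a root")
        if non_soma_roots:
            raise SwcFormatError(f"multiple roots: {sorted(roots)}")
    elif len(roots) > 1:
        raise SwcFormatError(f"multiple roots: {sorted(roots)}")

    def canon(sid: int) -> int:
        """Collapse soma samples onto the root sample id."""
        return roots[0] if sid in soma_ids else sid

    children: Dict[int, List[int]] = {}
    for sid in order:
        parent = samples[sid][5]
        if parent == -1:
            continue
        p, c = canon(parent), canon(sid)
        if p == c:  # soma-internal link
            continue
        children.setdefault(p, []).append(c)

    root_id = canon(roots[0])

    def pos(sid: int) -> Tuple[float, float, float]:
        _, x, y, z, _, _ = samples[sid]
        return (x, y, z)

    def radius(sid: int) -> float:
        return samples[sid][4]

    def seglen(u: int, v: int) -> float:
        (x1, y1, z1), (x2, y2, z2) = pos(u), pos(v)
        return math.dist((x1, y1, z1), (x2, y2, z2))

    # Chain-collapsing walk: branch points are samples with >= 2 children
    # (plus the root); leaves end chains.
    edges: List[Tuple[str, str, str, float, float]] = []

    def walk(start: int) -> None:
        for child in children.get(start, []):
            length = 0.0
            weighted_diam = 0.0
            prev = start
            cur = child
            while True:
                sl = seglen(prev, cur)
                seg_diam = radius(prev) + radius(cur)  # mean diameter = r1 + r2
                length += sl
                weighted_diam += sl * seg_diam
                kids = children.get(cur, [])
                if len(kids) != 1:
                    break
                if split_on_radius_change and radius(kids[0]) != radius(cur):
                    break
                prev, cur = cur, kids[0]
            if length <= 0:
                raise SwcFormatError(
                    f"zero-length chain ending at sample {cur}", lineno_of.get(cur)
                )
            diam = weighted_diam / length
            edges.append((str(cur), str(start), str(cur), length, diam))
            walk(cur)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(samples) + 100))
    try:
        walk(root_id)
    finally:
        sys.setrecursionlimit(old_limit)

    if not edges:
        raise SwcFormatError("morphology has no branches")

    node_ids = {str(root_id)}
    for _, u, v, _, _ in edges:
        node_ids.update((u, v))
    degree: Dict[str, int] = {nid: 0 for nid in node_ids}
    for _, u, v, _, _ in edges:
        degree[u] += 1
        degree[v] += 1
    nodes = [
        Node(nid, kind="terminal" if degree[nid] == 1 else "internal",
             boundary=params.boundary if degree[nid] == 1 else None)
        for nid in sorted(node_ids)
    ]
    branches = []
    for bid, u, v, L, a in edges:
        lam, tau, D, r = derive_electrotonic(L, a, params, bid)
        branches.append(Branch(bid, u, v, L, a, lam, D, tau, r))
    return Morphology(nodes, branches, params, root=str(root_id))


def write_swc(m: Morphology, stream: Optional[TextIO] = None) -> str:
    """Serialise a morphology to SWC text (also returned as a string).

    The tree is embedded in the z=0 plane with exact branch lengths.  Radii
    are assigned sample-by-sample so that the reader's mean-diameter rule
    reproduces every branch diameter: the radius of a child sample is the
    branch diameter minus the parent sample's radius.
    """
    sid_of: Dict[str, int] = {}
    lines = ["# generated by dtrips.swc.write_swc"]

    root_children = [(bid, other) for bid, other in m.neighbors(m.root)]
    if not root_children:
        raise ValueError("morphology has no branches")
    first_branch = m.branches[root_children[0][0]]

    positions: Dict[str, Tuple[float, float]] = {m.root: (0.0, 0.0)}
    radii: Dict[str, float] = {m.root: first_branch.a / 2.0}

    sid_of[m.root] = 1
    lines.append(f"1 1 0.0 0.0 0.0 {radii[m.root]:.9g} -1")
    counter = [1]

    def emit(node: str, parent: str, branch_id: str, angle: float, span: float) -> None:
        b = m.branches[branch_id]
        px, py = positions[parent]
        x, y = px + b.L * math.cos(angle), py + b.L * math.sin(angle)
        positions[node] = (x, y)
        r = b.a - radii[parent]
        if r <= 0:
            # fall back: bump the parent radius bookkeeping is not possible,
            # so clamp and accept a small diameter error for odd geometries
            r = b.a / 2.0
        radii[node] = r
        counter[0] += 1
        sid_of[node] = counter[0]
        lines.append(
            f"{sid_of[node]} 3 {x:.9g} {y:.9g} 0.0 {r:.9g} {sid_of[parent]}"
        )
        kids = [(bid, other) for bid, other in m.neighbors(node) if other != parent]
        nk = len(kids)
        for i, (bid, child) in enumerate(kids):
            child_angle = angle + span * ((i + 1) / (nk + 1) - 0.5)
            emit(child, node, bid, child_angle, span * 0.8)

    nk = len(root_children)
    for i, (bid, child) in enumerate(root_children):
        emit(child, m.root, bid, math.pi * (i / max(nk - 1, 1) - 0.0), math.pi / 2)

    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
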