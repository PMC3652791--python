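"""Monte-Carlo estimation of the Green's function by random walks on nodes.

A walk omega = (omega_1, ..., omega_kmax) starts at one of the two nodes
adjacent to the branch carrying x (each with probability 1/2) and steps from
node to node with transition probability p_k, the node factor of the branch
stepped onto.  Every prefix of the walk whose final step crosses the branch
carrying y is a trip x -> y; the indicator phi evaluates the free-space
kernel at that sub-trip's length, and the running product of importance
weights a~ converts path probability into the trip coefficient:

    A~(y, omega, t) = sum_k 2 phi(y, k, t, omega) prod_{i<=k} a~(i, omega)
    E[A~] = sum_{trips x->y, <= kmax - 1 nodes} A_trip Ginf(L_trip, t).

The weights are a~(1) = 1, and for a step k arriving at omega_k from the
node omega_{k-1}: 2 for a pass-through, (2 p_k - 1)/p_k for a reflection
(omega_{k-2} = omega_k), 1 at a closed terminal (priority).  A reflection at
step 2 means the walk returned along x's own branch, so the k = 2 weight
follows the same pass/reflect rule with x's branch playing the role of the
incoming edge; the leading factor 2 compensates the 1/2 first-step
probability.  Both conventions are fixed by the exact expectation identity
over the enumerable walk space, which is checked in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core import GreensSeries, ginf, node_factor, source_prefactor
from .enumeration import nudge_off_node
from .morphology import InvalidParameterError, Morphology, PointOnBranch

__all__ = [
    "WalkRealisation",
    "McEstimate",
    "sample_walk",
    "a_tilde",
    "phi",
    "walk_contribution",
    "estimate_greens",
    "exact_expectation",
    "default_kmax",
]


@dataclass(frozen=True)
class WalkRealisation:
    """A sampled node walk and the per-step transition probabilities used."""

    nodes: Tuple[str, ...]
    step_probs: Tuple[float, ...]


def sample_walk(
    m: Morphology, x: PointOnBranch, rng: np.random.Generator, kmax: int
) -> WalkRealisation:
    """Sample a walk of exactly ``kmax`` node hops starting beside x."""
    if kmax < 1:
        raise InvalidParameterError("kmax must be >= 1")
    u, v = m.endpoints(x.branch)
    first = u if rng.random() < 0.5 else v
    nodes = [first]
    probs = [0.5]
    cur = first
    for _ in range(kmax - 1):
        nbrs = m.neighbors(cur)
        ps = [node_factor(m, cur, bid) for bid, _ in nbrs]
        idx = rng.choice(len(nbrs), p=ps) if len(nbrs) > 1 else 0
        probs.append(ps[idx])
        cur = nbrs[idx][1]
        nodes.append(cur)
    return WalkRealisation(tuple(nodes), tuple(probs))


def a_tilde(m: Morphology, x: PointOnBranch, omega: Sequence[str], k: int) -> float:
    """Importance weight a~(k, omega) for the k-th step (1-based)."""
    if not 1 <= k <= len(omega):
        raise InvalidParameterError(f"step {k} outside walk of length {len(omega)}")
    if k == 1:
        return 1.0
    node = omega[k - 2]          # the node the k-th step departs from
    target = omega[k - 1]
    if m.is_terminal(node):
        # the only move is back; closed ends weigh 1, open ends -1
        return m.terminal_sign(node)
    if k == 2:
        # reflection iff the walk returns along x's own branch
        reflected = m.branch_between(node, target) == x.branch
    else:
        reflected = omega[k - 3] == target
    if not reflected:
        return 2.0
    p = node_factor(m, node, m.branch_between(node, target))
    return (2.0 * p - 1.0) / p


def _subtrip_length(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    omega: Sequence[str],
    k: int,
    cumlen: Optional[Sequence[float]] = None,
) -> float:
    """Electrotonic length of the sub-trip using the first k-1 nodes of omega."""
    length = m.point_segments(x)[omega[0]]
    if cumlen is not None:
        length += cumlen[k - 2]
    else:
        for i in range(k - 2):
            length += m.el(m.branch_between(omega[i], omega[i + 1]))
    length += m.point_segments(y)[omega[k - 2]]
    return length


def phi(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    omega: Sequence[str],
    k: int,
    t,
):
    """phi(y, k, t, omega): Ginf at the sub-trip length when the k-th step
    crosses y's branch, else 0."""
    if k < 2 or k > len(omega):
        return np.zeros_like(np.asarray(t, dtype=float))
    if {omega[k - 2], omega[k - 1]} != set(m.endpoints(y.branch)):
        return np.zeros_like(np.asarray(t, dtype=float))
    bj = m.branches[y.branch]
    L = _subtrip_length(m, x, y, omega, k)
    return ginf(L, t, bj.D, bj.tau)


def walk_contribution(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    omega: Sequence[str],
    t: np.ndarray,
) -> np.ndarray:
    """A~(y, omega, t): the summed weighted sub-trip kernels of one walk."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    bj = m.branches[y.branch]
    y_ends = set(m.endpoints(y.branch))
    x_segs = m.point_segments(x)
    y_segs = m.point_segments(y)
    prod = 1.0
    cum = 0.0
    for k in range(1, len(omega) + 1):
        prod *= a_tilde(m, x, omega, k)
        if prod == 0.0:
            break
        if k >= 2:
            if {omega[k - 2], omega[k - 1]} == y_ends:
                L = x_segs[omega[0]] + cum + y_segs[omega[k - 2]]
                out += 2.0 * prod * ginf(L, t, bj.D, bj.tau)
            cum += m.el(m.branch_between(omega[k - 2], omega[k - 1]))
    return out


@dataclass
class McEstimate:
    """Monte-Carlo Green's function with a per-time-point standard error."""

    series: GreensSeries
    stderr: np.ndarray
    n_walks: int
    kmax: int
    seed: Optional[int]


def default_kmax(m: Morphology, T: float) -> int:
    """Hops needed to cover the effective diffusion range 6 sqrt(4 T / tau)
    (electrotonic) at the smallest branch length."""
    min_el = min(m.el(b) for b in m.branches)
    span = 6.0 * math.sqrt(4.0 * T / m.tau)
    return max(2, int(math.ceil(span / min_el)) + 2)


def estimate_greens(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    t: np.ndarray,
    n_walks: int,
    kmax: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> McEstimate:
    """Estimate G_ij(x, y, t) as the walk average of A~ times 1/(pi a_j C)."""
    if n_walks < 1:
        raise InvalidParameterError("n_walks must be >= 1")
    x = nudge_off_node(m, x)
    y = nudge_off_node(m, y)
    if x.branch == y.branch:
        raise InvalidParameterError(
            "the walk estimator needs x and y on different branches; "
            "split the branch or use the matrix method"
        )
    t = np.asarray(t, dtype=float)
    if kmax is None:
        kmax = default_kmax(m, float(t[-1]))
    # can y's branch be crossed at all within kmax hops?
    du = m.node_distances(m.endpoints(x.branch)[0])
    dv = m.node_distances(m.endpoints(x.branch)[1])
    yu, yv = m.endpoints(y.branch)
    min_hops = 2 + min(
        len(m.node_path(s, g)) - 1
        for s in m.endpoints(x.branch)
        for g in (yu, yv)
    )
    if kmax < min_hops:
        warnings.warn(
            f"kmax={kmax} cannot reach y (needs >= {min_hops}); estimate is zero"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    mean = np.zeros_like(t)
    m2 = np.zeros_like(t)
    for i in range(1, n_walks + 1):
        walk = sample_walk(m, x, rng, kmax)
        contrib = walk_contribution(m, x, y, walk.nodes, t)
        delta = contrib - mean
        mean += delta / i
        m2 += delta * (contrib - mean)
    pref = source_prefactor(m, y.branch)
    stderr = pref * np.sqrt(m2 / max(n_walks - 1, 1) / n_walks)
    series = GreensSeries(
        t,
        pref * mean,
        x,
        y,
        {"method": "monte-carlo", "n_walks": n_walks, "kmax": kmax, "seed": seed},
    )
    return McEstimate(series, stderr, n_walks, kmax, seed)


def _all_walks(m: Morphology, x: PointOnBranch, kmax: int) -> Iterator[Tuple[Tuple[str, ...], float]]:
    """All walks of length kmax with their probabilities (oracle helper)."""
    u, v = m.endpoints(x.branch)
    stack: List[Tuple[Tuple[str, ...], float]] = [((u,), 0.5), ((v,), 0.5)]
    while stack:
        nodes, prob = stack.pop()
        if len(nodes) == kmax:
            yield nodes, prob
            continue
        cur = nodes[-1]
        for bid, nxt in m.neighbors(cur):
            stack.append((nodes + (nxt,), prob * node_factor(m, cur, bid)))


def exact_expectation(
    m: Morphology,
    x: PointOnBranch,
    y: PointOnBranch,
    t: np.ndarray,
    kmax: int,
) -> GreensSeries:
    """Exact E[A~] over the full walk space (exponential in kmax).

    Equals the trip series truncated to kmax - 1 node visits; used as the
    unbiasedness oracle for the sampler.
    """
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for nodes, prob in _all_walks(m, x, kmax):
        total += prob * walk_contribution(m, x, y, nodes, t)
    total *= source_prefactor(m, y.branch)
    return GreensSeries(t, total, x, y, {"method": "mc-exact", "kmax": kmax})
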