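"""Sorting signed permutations by reversals (paracentric inversions).

The order and orientation of conserved syntenic segments along a chromosome,
written as a signed permutation, determines the minimum number of inversions
separating two arrangements.  This module implements the Hannenhalli-Pevzner
theory in full:

    d(pi) = (n + 1) - c(pi) + h(pi) + f(pi)

where ``c`` counts the alternating cycles of the breakpoint graph over the
framed, doubled permutation, ``h`` counts hurdles among the unoriented
components, and ``f`` is 1 exactly for a fortress (an odd number of hurdles,
all of them superhurdles).  The cycle-only lower bound is wrong already for
all-positive permutations such as (+3, +2, +1), hence the full treatment.

An exhaustive breadth-first-search oracle over the reversal graph
(:func:`bfs_distance_oracle`) provides an independent check for small n, and
:func:`sorting_scenario` returns one optimal scenario with deterministic
(lexicographically smallest) tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial
from typing import Sequence

import numpy as np

__all__ = [
    "SignedPermutation",
    "BreakpointGraph",
    "Reversal",
    "breakpoint_graph",
    "reversal_distance",
    "bfs_distance_oracle",
    "sorting_scenario",
    "apply_reversal",
    "subtract_inversions",
    "breakpoint_reuse",
]


@dataclass(frozen=True)
class SignedPermutation:
    """An ordering of n signed segments; absolute values are exactly 1..n."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        n = len(vals)
        if sorted(abs(v) for v in vals) != list(range(1, n + 1)):
            raise ValueError("absolute values must be exactly 1..n, each once")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def is_identity(self) -> bool:
        return all(v == i + 1 for i, v in enumerate(self.values))

    def inverse(self) -> "SignedPermutation":
        out = [0] * self.n
        for pos, v in enumerate(self.values, start=1):
            out[abs(v) - 1] = pos if v > 0 else -pos
        return SignedPermutation(tuple(out))

    def reflect(self) -> "SignedPermutation":
        """Read the chromosome from the other end.

        Order reverses and every orientation flips, but the reference frame
        reflects too (segment i becomes segment n+1-i), so the two sign
        flips cancel: entry k becomes sign(v) * (n+1-|v|) for v at position
        n+1-k.  Distance is invariant under this transform.
        """
        n = self.n
        return SignedPermutation(
            tuple(
                (1 if v > 0 else -1) * (n + 1 - abs(v))
                for v in reversed(self.values)
            )
        )


@dataclass(frozen=True)
class Reversal:
    """1-based inclusive index interval [i, j] to reverse and negate."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i <= self.j):
            raise ValueError(f"invalid reversal interval ({self.i}, {self.j})")


@dataclass(frozen=True)
class BreakpointGraph:
    cycles: int
    breakpoints: int
    hurdles: int
    fortress: int


def apply_reversal(p: SignedPermutation, r: Reversal) -> SignedPermutation:
    if r.j > p.n:
        raise ValueError(f"reversal ({r.i}, {r.j}) out of range for n={p.n}")
    v = list(p.values)
    v[r.i - 1 : r.j] = [-x for x in reversed(v[r.i - 1 : r.j])]
    return SignedPermutation(tuple(v))


def _framed(p: SignedPermutation) -> list[int]:
    """Framed doubling: +x -> (2x-1, 2x); -x -> (2x, 2x-1); caps 0, 2n+1."""
    out = [0]
    for v in p.values:
        x = abs(v)
        out.extend((2 * x - 1, 2 * x) if v > 0 else (2 * x, 2 * x - 1))
    out.append(2 * p.n + 1)
    return out


def _graph_elements(p: SignedPermutation):
    """Cycles of the breakpoint graph and the gray edges of each cycle.

    Returns ``(n_cycles, n_adjacencies, cycle_edges)`` where ``cycle_edges``
    lists, for each nontrivial cycle, its gray edges as position pairs
    ``(i, j)`` with ``i < j`` in the framed sequence.
    """
    u = _framed(p)
    n = p.n
    pos = [0] * (2 * n + 2)
    for idx, val in enumerate(u):
        pos[val] = idx
    # black partner: framed positions (2i, 2i+1) for i in 0..n
    black = [0] * (2 * n + 2)  # value -> value joined by black edge
    for i in range(n + 1):
        a, b = u[2 * i], u[2 * i + 1]
        black[a] = b
        black[b] = a
    # gray partner: values (2i, 2i+1)
    gray = [0] * (2 * n + 2)
    for i in range(n + 1):
        gray[2 * i] = 2 * i + 1
        gray[2 * i + 1] = 2 * i
    seen = [False] * (2 * n + 2)
    n_cycles = 0
    n_adj = 0
    cycle_edges: list[list[tuple[int, int]]] = []
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        n_cycles += 1
        edges: list[tuple[int, int]] = []
        v = start
        length = 0
        while True:
            # traverse black then gray
            seen[v] = True
            w = black[v]
            seen[w] = True
            x = gray[w]
            i, j = pos[w], pos[x]
            edges.append((min(i, j), max(i, j)))
            length += 1
            v = x
            if v == start:
                break
        if length == 1:
            n_adj += 1
        else:
            cycle_edges.append(edges)
    return n_cycles, n_adj, cycle_edges


def _components(cycle_edges: list[list[tuple[int, int]]]):
    """Connected components of the cycle-interleaving graph.

    Two cycles belong to one component when any of their gray edges
    interleave; a component is oriented when it contains an oriented gray
    edge (framed positions of equal parity).
    """
    k = len(cycle_edges)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a in range(k):
        for b in range(a + 1, k):
            done = False
            for i1, j1 in cycle_edges[a]:
                for i2, j2 in cycle_edges[b]:
                    if i1 < i2 < j1 < j2 or i2 < i1 < j2 < j1:
                        union(a, b)
                        done = True
                        break
                if done:
                    break
    comps: dict[int, dict] = {}
    for idx in range(k):
        root = find(idx)
        comp = comps.setdefault(root, {"edges": [], "oriented": False})
        comp["edges"].extend(cycle_edges[idx])
    for comp in comps.values():
        comp["span"] = (
            min(i for i, _ in comp["edges"]),
            max(j for _, j in comp["edges"]),
        )
        comp["oriented"] = any((j - i) % 2 == 0 for i, j in comp["edges"])
    return list(comps.values())


def _hurdles_among(spans: list[tuple[int, int]]) -> list[int]:
    """Indices of hurdles among unoriented component spans (circle order).

    Spans of distinct components are disjoint or nested.  A hurdle is a
    component whose arc on the circle contains no other unoriented
    component: the nesting-minimal components, plus the maximal component
    when it contains every other one (its complementary arc is empty).
    """
    out = []
    m = len(spans)
    for a in range(m):
        sa, ea = spans[a]
        contains_other = any(
            b != a and sa <= spans[b][0] and spans[b][1] <= ea for b in range(m)
        )
        if not contains_other:
            out.append(a)  # minimal
        elif all(sa <= spans[b][0] and spans[b][1] <= ea for b in range(m) if b != a):
            out.append(a)  # greatest: all others inside, complement arc empty
    return out


def _hurdles_fortress(components) -> tuple[int, int]:
    unoriented = [c for c in components if not c["oriented"]]
    if not unoriented:
        return 0, 0
    spans = [c["span"] for c in unoriented]
    hurdle_idx = _hurdles_among(spans)
    h = len(hurdle_idx)
    if h < 3 or h % 2 == 0:
        return h, 0
    # fortress: odd number of hurdles, every one a superhurdle.  H is a
    # superhurdle when deleting it promotes a previously-non-hurdle
    # unoriented component to hurdle status.
    hurdle_set = set(hurdle_idx)
    for hi in hurdle_idx:
        rest = [spans[b] for b in range(len(spans)) if b != hi]
        rest_ids = [b for b in range(len(spans)) if b != hi]
        new_hurdles = {rest_ids[x] for x in _hurdles_among(rest)}
        if not (new_hurdles - hurdle_set):
            return h, 0  # hi is a simple hurdle
    return h, 1


def breakpoint_graph(p: SignedPermutation) -> BreakpointGraph:
    """Cycle, breakpoint, hurdle and fortress counts of the framed graph."""
    n_cycles, n_adj, cycle_edges = _graph_elements(p)
    h, f = _hurdles_fortress(_components(cycle_edges))
    return BreakpointGraph(
        cycles=n_cycles,
        breakpoints=(p.n + 1) - n_adj,
        hurdles=h,
        fortress=f,
    )


def reversal_distance(p: SignedPermutation) -> int:
    """Minimum number of reversals transforming p into the identity."""
    g = breakpoint_graph(p)
    return p.n + 1 - g.cycles + g.hurdles + g.fortress


def sorting_scenario(p: SignedPermutation) -> list[Reversal]:
    """One optimal sorting scenario, deterministic tie-breaking.

    At every step the lexicographically smallest reversal that decreases the
    exact distance by one is applied; such a reversal always exists on an
    optimal path, so the scenario length equals :func:`reversal_distance`.
    """
    scenario: list[Reversal] = []
    cur = p
    d = reversal_distance(cur)
    while d > 0:
        found = None
        for i in range(1, cur.n + 1):
            for j in range(i, cur.n + 1):
                r = Reversal(i, j)
                q = apply_reversal(cur, r)
                if reversal_distance(q) == d - 1:
                    found = (r, q)
                    break
            if found:
                break
        if found is None:  # pragma: no cover - contradicts HP theory
            raise RuntimeError("no distance-reducing reversal found")
        scenario.append(found[0])
        cur = found[1]
        d -= 1
    return scenario


def subtract_inversions(
    p: SignedPermutation, known: Sequence[Reversal]
) -> SignedPermutation:
    """Un-apply a known lineage's inversions from a relative arrangement.

    ``p`` expresses the target genome in the known lineage's segment frame
    (segment labels are positions along that lineage's chromosome) and
    ``known`` lists the inversions fixed on that lineage since the common
    ancestor, in order of application, as index intervals on its evolving
    arrangement.  The result expresses the target genome in the ancestral
    frame, so its distance to identity counts only the inversions fixed in
    the target's own lineage.
    """
    vals = list(p.values)
    n = p.n
    for r in reversed(list(known)):
        if r.j > n:
            raise ValueError(f"reversal ({r.i}, {r.j}) out of range for n={n}")
        out = []
        for v in vals:
            if r.i <= abs(v) <= r.j:
                out.append(-int(np.sign(v)) * (r.i + r.j - abs(v)))
            else:
                out.append(v)
        vals = out
    return SignedPermutation(tuple(vals))


def breakpoint_reuse(d: int, distinct_breakpoints: int) -> int:
    """Number of reused breakpoints: 2d - (distinct breakpoints)."""
    if d < 0 or distinct_breakpoints < 0:
        raise ValueError("counts must be non-negative")
    reuse = 2 * d - distinct_breakpoints
    if reuse < 0:
        raise ValueError(
            f"inconsistent inputs: 2*{d} < {distinct_breakpoints} distinct breakpoints"
        )
    return reuse


# --- exhaustive BFS oracle -------------------------------------------------


def _perm_rank(perm: Sequence[int]) -> int:
    """Lehmer rank of an unsigned permutation of 1..n."""
    n = len(perm)
    rank = 0
    items = list(perm)
    for i in range(n):
        smaller = sum(1 for x in items[i + 1 :] if x < items[i])
        rank = rank * (n - i) + smaller
    return rank


def encode_state(values: Sequence[int]) -> int:
    n = len(values)
    signs = 0
    for i, v in enumerate(values):
        if v < 0:
            signs |= 1 << i
    return _perm_rank([abs(v) for v in values]) * (1 << n) + signs


def _build_table_python(n: int) -> np.ndarray:
    from itertools import permutations

    size = factorial(n) * (1 << n)
    dist = np.full(size, 255, dtype=np.uint8)
    identity = tuple(range(1, n + 1))
    start = encode_state(identity)
    dist[start] = 0
    frontier = [identity]
    d = 0
    while frontier:
        nxt = []
        for state in frontier:
            for i in range(n):
                for j in range(i, n):
                    child = (
                        state[:i]
                        + tuple(-x for x in reversed(state[i : j + 1]))
                        + state[j + 1 :]
                    )
                    code = encode_state(child)
                    if dist[code] == 255:
                        dist[code] = d + 1
                        nxt.append(child)
        frontier = nxt
        d += 1
    return dist


def _build_table_numba(n: int) -> np.ndarray:
    from numba import njit

    @njit(cache=False)
    def build(n):
        fact = 1
        for i in range(2, n + 1):
            fact *= i
        size = fact * (1 << n)
        dist = np.full(size, 255, dtype=np.uint8)
        # states stored as int64: element e in 4 bits each (1..n), sign bits low
        def pack(vals_abs, signs):
            rank = 0
            for i in range(n):
                smaller = 0
                for jj in range(i + 1, n):
                    if vals_abs[jj] < vals_abs[i]:
                        smaller += 1
                rank = rank * (n - i) + smaller
            return rank * (1 << n) + signs

        identity = np.arange(1, n + 1, dtype=np.int8)
        frontier = np.empty((1, n), dtype=np.int8)
        frontier[0] = identity
        dist[pack(identity, 0)] = 0
        d = 0
        while frontier.shape[0] > 0:
            cap = frontier.shape[0] * (n * (n + 1)) // 2
            nxt = np.empty((cap, n), dtype=np.int8)
            cnt = 0
            for si in range(frontier.shape[0]):
                state = frontier[si]
                for i in range(n):
                    for j in range(i, n):
                        child = state.copy()
                        for t in range((j - i + 1) // 2 + ((j - i + 1) % 2)):
                            a = i + t
                            b = j - t
                            if a < b:
                                tmp = child[a]
                                child[a] = -child[b]
                                child[b] = -tmp
                            elif a == b:
                                child[a] = -child[a]
                        vals_abs = np.empty(n, dtype=np.int8)
                        signs = 0
                        for t in range(n):
                            v = child[t]
                            if v < 0:
                                vals_abs[t] = -v
                                signs |= 1 << t
                            else:
                                vals_abs[t] = v
                        code = pack(vals_abs, signs)
                        if dist[code] == 255:
                            dist[code] = d + 1
                            nxt[cnt] = child
                            cnt += 1
            frontier = nxt[:cnt].copy()
            d += 1
        return dist

    return build(n)


@lru_cache(maxsize=8)
def _distance_table(n: int) -> np.ndarray:
    if n >= 7:
        try:
            return _build_table_numba(n)
        except ImportError:  # pragma: no cover - numba is a declared dependency
            pass
    return _build_table_python(n)


def bfs_distance_oracle(p: SignedPermutation, max_n: int = 8) -> int:
    """Exact reversal distance by breadth-first search over the state space.

    Independent of the breakpoint-graph machinery: enumerates the reversal
    graph outward from the identity (reversals are involutions, so distance
    to and from the identity coincide).  Capacity-limited to ``max_n``.
    """
    if p.n > max_n:
        raise ValueError(f"oracle capacity exceeded: n={p.n} > max_n={max_n}")
    table = _distance_table(p.n)
    return int(table[encode_state(p.values)])
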