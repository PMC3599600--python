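"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive substring enumeration,
fully expanded regular expressions, breadth-first path sums — so that it
shares no code path with the implementations under test.
"""
from __future__ import annotations

import itertools
import re

import numpy as np

_SIGN = {"K": 1, "R": 1, "D": -1, "E": -1}


def stretch_rule(sub: str, sign: int, mode: str) -> bool:
    """Direct statement of the charged-stretch rule for one substring."""
    signs = [_SIGN.get(c, 0) for c in sub]
    if any(s == -sign for s in signs):
        return False
    if not signs or signs[0] != sign or signs[-1] != sign:
        return False
    gaps = signs.count(0)
    if gaps == 0:
        return len(sub) >= 3
    if gaps == 1:
        return len(sub) >= (5 if mode == "strict" else 4)
    return False


def brute_force_stretches(seq: str, mode: str = "strict") -> set[tuple[int, int, str]]:
    """Every maximal substring satisfying the rule, by exhaustive enumeration."""
    n = len(seq)
    hits: set[tuple[int, int, str]] = set()
    for sign, label in ((1, "positive"), (-1, "negative")):
        cands = [
            (i, j)
            for i in range(n)
            for j in range(i, n)
            if stretch_rule(seq[i : j + 1], sign, mode)
        ]
        cand_set = set(cands)
        for i, j in cands:
            contained = any(
                (a, b) in cand_set
                for a in range(i + 1)
                for b in range(j, n)
                if (a, b) != (i, j)
            )
            if not contained:
                hits.add((i + 1, j + 1, label))
    return hits


def regex_extents(seq: str, pattern) -> set[tuple[int, int]]:
    """All (start, end) extents of a MotifPattern via expanded regexes."""
    extents: set[tuple[int, int]] = set()
    repeat_ranges = [range(lo, hi + 1) for _, lo, hi in pattern.elements]
    for combo in itertools.product(*repeat_ranges):
        parts = []
        for (cls, _, _), rep in zip(pattern.elements, combo):
            parts.append("[" + "".join(sorted(cls)) + "]" + "{%d}" % rep)
        rx = re.compile("(?=(" + "".join(parts) + "))")
        for m in rx.finditer(seq):
            extents.add((m.start(1) + 1, m.end(1)))
    return extents


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree with positive branch lengths.

    Returns (distance matrix over leaves L0..L{n-1}, set of canonical leaf
    bipartitions).  Distances are exact path-length sums.
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    next_internal = [0]

    def new_internal() -> str:
        next_internal[0] += 1
        return f"_i{next_internal[0]}"

    # adjacency: node -> {neighbor: length}
    adj: dict[str, dict[str, float]] = {}

    def connect(a: str, b: str, length: float) -> None:
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    def disconnect(a: str, b: str) -> float:
        length = adj[a].pop(b)
        adj[b].pop(a)
        return length

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    center = new_internal()
    for leaf in labels[:3]:
        connect(center, leaf, blen())
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        old = disconnect(a, b)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        connect(a, mid, old * split)
        connect(mid, b, old * (1 - split))
        connect(mid, labels[labels.index(leaf)], blen())

    # path lengths by BFS from each leaf
    dist = np.zeros((n_leaves, n_leaves))
    index = {l: i for i, l in enumerate(labels)}
    for leaf in labels:
        seen = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for other in labels:
            dist[index[leaf], index[other]] = seen[other]
    dist = 0.5 * (dist + dist.T)  # exact symmetry despite float addition order

    # canonical bipartitions: for each internal edge, leaves on one side
    anchor = min(labels)
    bips = set()
    internal_edges = [
        (a, b) for a in adj for b in adj[a]
        if a.startswith("_i") and b.startswith("_i") and a < b
    ]
    for a, b in internal_edges:
        length = disconnect(a, b)
        side = set()
        stack = [b]
        seen_nodes = {b}
        while stack:
            u = stack.pop()
            if not u.startswith("_i"):
                side.add(u)
            for v in adj[u]:
                if v not in seen_nodes:
                    seen_nodes.add(v)
                    stack.append(v)
        connect(a, b, length)
        if anchor in side:
            side = set(labels) - side
        if 1 < len(side) < n_leaves - 1:
            bips.add(frozenset(side))
    return labels, dist, bips
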