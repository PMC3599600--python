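"""Distance phylogenies per region: p-distance, neighbor joining, bootstrap.

Distances are p-distances (mismatch fraction over pairwise-comparable,
gap-free columns).  Trees are classical neighbor-joining (Q-criterion)
unrooted binary trees, exact on additive matrices; bootstrap resamples
alignment columns with replacement and scores each internal edge by the
percentage of replicate trees containing the same leaf bipartition.  Class
partitions group families separated by well-supported edges — the device
used to compare full-length against N-arm and C-arm groupings.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .seqio import AlignmentBlock
from .segmentation import RegionAnnotation, _column_map

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal; NaN marks missing pairs
    comparable: Optional[np.ndarray] = None  # per-pair compared column counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, rid in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{rid}  {row}\n")


@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf id; None for internal nodes
    length: float = 0.0  # branch above this node
    support: Optional[float] = None  # bootstrap percentage of the edge above
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted binary tree stored with a degree-3 root."""

    root: TreeNode
    clamped_deficit: float = 0.0  # total negative branch length clamped to zero

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def _internal_edges(self) -> list[TreeNode]:
        """Internal nodes other than the root; each owns the edge above it."""
        out = []

        def walk(node: TreeNode) -> None:
            for ch in node.children:
                if not ch.is_leaf:
                    out.append(ch)
                walk(ch)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Canonical leaf bipartitions of the internal edges.

        Each edge is keyed by the side not containing the lexicographically
        smallest leaf, so keys are comparable across trees on the same taxa.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out = {}
        for node in self._internal_edges():
            side = frozenset(node.leaves())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node
        return out

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# Distances


def _scope_columns(
    alignment: AlignmentBlock,
    scope: str,
    annotations: Optional[Mapping[str, RegionAnnotation]],
    reference_id: Optional[str],
) -> np.ndarray:
    """Columns belonging to a scope: everything left (N) or right (C) of the
    core's projected column span."""
    if scope == "full":
        return np.arange(alignment.length)
    if annotations is None or reference_id is None:
        raise ValueError("N/C scope needs annotations and a reference_id")
    ann = annotations[reference_id]
    if ann.core is None:
        raise ValueError(f"reference {reference_id} is unsegmentable")
    cols = _column_map(alignment.row(reference_id))
    c1, c2 = cols[ann.core[0] - 1], cols[ann.core[1] - 1]
    out = np.arange(0, c1) if scope == "N" else np.arange(c2 + 1, alignment.length)
    if out.size == 0:
        raise ValueError(f"no columns in scope {scope}")
    return out


def _encode(alignment: AlignmentBlock, rows: Sequence[str], columns: np.ndarray):
    mat = np.vstack(
        [np.frombuffer(alignment.row(r).encode("ascii"), dtype=np.uint8) for r in rows]
    )[:, columns]
    nongap = mat != ord("-")
    return mat, nongap


def p_distance(
    alignment: AlignmentBlock,
    scope: str = "full",
    annotations: Optional[Mapping[str, RegionAnnotation]] = None,
    reference_id: Optional[str] = None,
    rows: Optional[Sequence[str]] = None,
    min_comparable: int = 10,
    saturate_missing: bool = False,
) -> DistanceMatrix:
    """Pairwise p-distance over the scope's columns with pairwise deletion.

    Pairs with no comparable (mutually gap-free) column are an error; pairs
    with fewer than ``min_comparable`` are flagged missing (NaN).  With
    ``saturate_missing`` both cases instead receive the maximum distance 1.0
    — the convention for arm blocks that are not mutually alignable.
    """
    if rows is None:
        rows = alignment.ids
    cols = _scope_columns(alignment, scope, annotations, reference_id)
    mat, nongap = _encode(alignment, rows, cols)
    eq = (mat[:, None, :] == mat[None, :, :]) & nongap[:, None, :] & nongap[None, :, :]
    matches = eq.sum(axis=2).astype(float)
    valid = (nongap.astype(np.int64) @ nongap.T.astype(np.int64)).astype(float)
    empty = np.argwhere(valid == 0)
    empty = empty[empty[:, 0] < empty[:, 1]]
    if empty.size and not saturate_missing:
        i, j = empty[0]
        raise ValueError(
            f"no comparable columns for pair ({rows[i]}, {rows[j]}) in scope {scope}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - matches / np.where(valid > 0, valid, 1.0)
    d[valid < min_comparable] = 1.0 if saturate_missing else np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(rows), d, comparable=valid)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ agglomeration; deterministic, exact on additive matrices.

    Ties in the Q criterion are broken toward the lexicographically smallest
    (cluster key) pair, where a cluster's key is its smallest leaf id.
    Negative estimated branch lengths are clamped to zero with the deficit
    accumulated on the returned tree.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains missing entries")
    D = dm.values.astype(float).copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    keys = list(dm.ids)
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # float addition order makes Q asymmetric in the last bit; search the
        # upper triangle only so each pair is judged by a single value
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        cand = np.argwhere(Q == qmin)
        i, j = min(cand, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(float(li))
        child_j.length = clamp(float(lj))
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = dnew[keep]
        D[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(float((dab + dac - dbc) / 2))
    b.length = clamp(float((dab + dbc - dac) / 2))
    c.length = clamp(float((dac + dbc - dab) / 2))
    root = TreeNode(children=[a, b, c])
    if deficit:
        logger.info("clamped %.6g of negative branch length to zero", deficit)
    return PhyloTree(root, clamped_deficit=deficit)


# ---------------------------------------------------------------------------
# Bootstrap


def _weighted_distance(eqf: np.ndarray, G: np.ndarray, w: np.ndarray,
                       ids: tuple[str, ...]) -> DistanceMatrix:
    n = len(ids)
    matches = (eqf @ w).reshape(n, n)
    valid = (G * w) @ G.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(valid > 0, 1.0 - matches / np.where(valid > 0, valid, 1.0), 1.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


def bootstrap_support(
    alignment: AlignmentBlock,
    scope: str = "full",
    B: int = 100,
    seed: int = 0,
    annotations: Optional[Mapping[str, RegionAnnotation]] = None,
    reference_id: Optional[str] = None,
    rows: Optional[Sequence[str]] = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Deterministic given ``seed``.  Supports are percentages in [0, 100] on
    every internal edge of the tree built from the original columns.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rows is None:
        rows = alignment.ids
    ids = tuple(rows)
    cols = _scope_columns(alignment, scope, annotations, reference_id)
    mat, nongap = _encode(alignment, rows, cols)
    n, L = mat.shape
    eq = (mat[:, None, :] == mat[None, :, :]) & nongap[:, None, :] & nongap[None, :, :]
    eqf = eq.reshape(n * n, L).astype(np.float32)
    G = nongap.astype(np.float32)

    base = neighbor_joining(_weighted_distance(eqf, G, np.ones(L, dtype=np.float32), ids))
    base_bips = base.bipartitions()
    counts = {bip: 0 for bip in base_bips}

    rng = np.random.default_rng(seed)
    for _ in range(B):
        draws = rng.integers(0, L, size=L)
        w = np.bincount(draws, minlength=L).astype(np.float32)
        rep = neighbor_joining(_weighted_distance(eqf, G, w, ids))
        rep_bips = set(rep.bipartitions())
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in base_bips.items():
        node.support = 100.0 * counts[bip] / B
    return base


# ---------------------------------------------------------------------------
# Class partitions


@dataclass
class ClassPartition:
    scope: str
    classes: dict[str, str]  # family -> class label
    purity: dict[str, float]  # family -> min majority fraction over used edges

    def groups(self) -> list[frozenset[str]]:
        by_label: dict[str, set[str]] = {}
        for fam, label in self.classes.items():
            by_label.setdefault(label, set()).add(fam)
        return sorted((frozenset(v) for v in by_label.values()), key=lambda g: min(g))


def _family_patristic(tree: PhyloTree, family_labels: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Mean leaf-to-leaf path length between each family pair."""
    families = sorted(set(family_labels[l] for l in tree.leaf_names))
    idx = {f: i for i, f in enumerate(families)}
    m = len(families)
    sums = np.zeros((m, m))
    counts = np.zeros((m, m))

    def walk(node: TreeNode) -> dict[str, list[float]]:
        """family -> distances of the subtree's leaves to this node."""
        if node.is_leaf:
            return {family_labels[node.name]: [0.0]}
        merged: dict[str, list[float]] = {}
        for child in node.children:
            below = walk(child)
            below = {f: [d + child.length for d in ds] for f, ds in below.items()}
            for fa, da in merged.items():
                for fb, db in below.items():
                    i, j = idx[fa], idx[fb]
                    total = sum(da) * len(db) + sum(db) * len(da)
                    sums[i, j] += total
                    sums[j, i] += total
                    counts[i, j] += len(da) * len(db)
                    counts[j, i] += len(da) * len(db)
            for fb, db in below.items():
                merged.setdefault(fb, []).extend(db)
        return merged

    walk(tree.root)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), 0.0)
    np.fill_diagonal(mean, 0.0)
    return families, mean


def partition_classes(
    tree: PhyloTree,
    family_labels: Mapping[str, str],
    k_cut: float = 70.0,
    scope: str = "full",
    gap_ratio: float = 1.2,
) -> ClassPartition:
    """Group families into classes read off the tree's deep structure.

    Families are clustered by single linkage on mean patristic distance; the
    class level is the largest gap in the merge heights (required to exceed
    ``gap_ratio`` relative separation, otherwise no class structure is
    declared).  A split between two classes is kept only when some internal
    edge with bootstrap support >= ``k_cut`` (edges without a support value
    count as supported) separates their families by majority side; otherwise
    the classes are merged back.  Purity reports, per family, the smallest
    majority fraction over the class-separating edges — 1.0 for families
    whose leaves never straddle a class boundary.
    """
    leaves = tree.leaf_names
    missing = [l for l in leaves if l not in family_labels]
    if missing:
        raise ValueError(f"leaves without family label: {missing[:3]}")
    families, P = _family_patristic(tree, family_labels)
    m = len(families)
    purity = {f: 1.0 for f in families}
    if m == 1:
        return ClassPartition(scope, {families[0]: "class1"}, purity)

    # single-linkage merge heights
    active: list[set[int]] = [{i} for i in range(m)]
    merges: list[tuple[float, set[int], set[int]]] = []
    work = P.copy()
    np.fill_diagonal(work, np.inf)
    while len(active) > 1:
        best = (np.inf, 0, 1)
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                h = min(work[a, b] for a in active[i] for b in active[j])
                if h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merges.append((h, active[i], active[j]))
        active = [g for k, g in enumerate(active) if k not in (i, j)] + [active[i] | active[j]]

    heights = [h for h, _, _ in merges]
    if m == 2:
        threshold = heights[0] / 2
    else:
        gaps = [heights[k + 1] - heights[k] for k in range(len(heights) - 1)]
        k_star = int(np.argmax(gaps))
        significant = heights[k_star + 1] > gap_ratio * max(heights[k_star], 1e-12)
        threshold = (
            (heights[k_star] + heights[k_star + 1]) / 2 if significant else np.inf
        )

    # clusters = single-linkage components at the threshold
    groups: list[set[int]] = [{i} for i in range(m)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                h = min(P[a, b] for a in groups[i] for b in groups[j])
                if h <= threshold:
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break

    # supported family bipartitions (majority side per family)
    fam_sizes = {f: sum(1 for l in leaves if family_labels[l] == f) for f in families}
    supported_bips: list[tuple[frozenset[str], frozenset[str], dict[str, float]]] = []
    for side, node in tree.bipartitions().items():
        if node.support is not None and node.support < k_cut:
            continue
        inside_counts = {f: 0 for f in families}
        for leaf in side:
            inside_counts[family_labels[leaf]] += 1
        fam_in, fam_out, majority = set(), set(), {}
        for f in families:
            frac = inside_counts[f] / fam_sizes[f]
            (fam_in if frac >= 0.5 else fam_out).add(f)
            majority[f] = max(frac, 1 - frac)
        if fam_in and fam_out:
            supported_bips.append((frozenset(fam_in), frozenset(fam_out), majority))

    def separated(ga: set[int], gb: set[int]) -> Optional[dict[str, float]]:
        fa = {families[i] for i in ga}
        fb = {families[i] for i in gb}
        for fin, fout, majority in supported_bips:
            if (fa <= fin and fb <= fout) or (fa <= fout and fb <= fin):
                return majority
        return None

    # merge back class pairs lacking a supported separating edge; track purity
    merged_any = True
    while merged_any and len(groups) > 1:
        merged_any = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if separated(groups[i], groups[j]) is None:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged_any = True
                    break
            if merged_any:
                break
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            majority = separated(groups[i], groups[j])
            if majority:
                for f in majority:
                    purity[f] = min(purity[f], majority[f])

    groups_sorted = sorted((sorted(families[i] for i in g) for g in groups), key=lambda g: g[0])
    classes = {}
    for label_idx, g in enumerate(groups_sorted, start=1):
        for f in g:
            classes[f] = f"class{label_idx}"
    return ClassPartition(scope, classes, purity)
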