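"""p-distances, neighbor-joining trees and bootstrap support.

Distances follow the "pairwise deletion" convention: for each pair of
aligned rows, every column where either symbol is not a concrete base
(gap, N, IUPAC degeneracy) is removed before the proportion of differing
sites is computed.  Trees are built with the Saitou-Nei neighbor-joining
agglomeration with deterministic tie-breaking; negative branch lengths are
clamped to zero and flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .align import DEFAULT_PARAMS, align_pair
from .core import AlignParams

_BASES = frozenset("ACGT")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned rows.

    Positions where either row has a gap, N or ambiguity code are excluded
    (pairwise deletion).  Raises if no comparable position remains.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    comparable = 0
    diff = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        raise ValueError("no overlap: zero comparable positions")
    return diff / comparable


def pairwise_p_distance(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """p-distance of two unaligned sequences after global alignment."""
    ra, rb, _ = align_pair(a, b, params)
    return p_distance(ra, rb)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("matrix must be non-negative with zero diagonal")

    @classmethod
    def from_sequences(
        cls,
        labels: list[str],
        sequences: list[str],
        params: AlignParams = DEFAULT_PARAMS,
        aligned: bool = False,
    ) -> "DistanceMatrix":
        n = len(labels)
        values = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = (
                p_distance(sequences[i], sequences[j])
                if aligned
                else pairwise_p_distance(sequences[i], sequences[j], params)
            )
            values[i, j] = values[j, i] = d
        return cls(labels=labels, values=values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted at an arbitrary internal node) tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap % for the edge above this node
    clamped: bool = False  # true if the edge above had a negative NJ length

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self, length: float | None = None) -> str:
        if self.is_leaf():
            body = self.name or ""
        else:
            inner = ",".join(c._newick_node(l) for c, l in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            body = f"({inner}){label}"
        return body if length is None else f"{body}:{length:.10g}"


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (one side each), as frozensets."""
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(min(below, all_leaves - below, key=sorted))
            return below

        for child, _ in self.root.children:
            walk(child)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise path lengths between leaves (for additivity checks)."""
        names = self.leaf_names
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        values = np.zeros((n, n))

        def walk(node: TreeNode, dist: float, acc: dict[str, float]) -> None:
            if node.is_leaf():
                acc[node.name] = dist
                return
            for child, length in node.children:
                walk(child, dist + length, acc)

        # distances via root paths: d(a,b) = depth(a)+depth(b)-2*depth(lca)
        def pairs(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            sub = []
            for child, length in node.children:
                depths = pairs(child)
                sub.append({k: v + length for k, v in depths.items()})
            for da, db in itertools.combinations(sub, 2):
                for a, x in da.items():
                    for b, y in db.items():
                        values[index[a], index[b]] = values[index[b], index[a]] = x + y
            merged: dict[str, float] = {}
            for d in sub:
                merged.update(d)
            return merged

        pairs(self.root)
        return DistanceMatrix(labels=names, values=values)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (Saitou-Nei) with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) label pair of the joined clusters.  Negative branch lengths are
    clamped to zero and flagged on the node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels for a neighbor-joining tree")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    names: list[str] = list(dm.labels)  # cluster sort keys for tie-breaks
    d = dm.values.astype(float).copy()
    active = list(range(n))
    edge_len: dict[int, float] = {}  # node idx -> length of edge above it
    all_nodes = list(nodes)

    def attach(parent: TreeNode, child_idx: int, length: float) -> None:
        node = all_nodes[child_idx]
        if length < 0:
            node.clamped = True
            length = 0.0
        parent.children.append((node, length))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ii, jj in zip(*np.where(np.isclose(q, qmin))):
            if ii >= jj:
                continue
            i, j = active[ii], active[jj]
            key = tuple(sorted((names[i], names[j])))
            if best is None or key < best[0]:
                best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        li = 0.5 * sub[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = sub[ii, jj] - li
        parent = TreeNode()
        attach(parent, i, li)
        attach(parent, j, lj)
        new_idx = len(all_nodes)
        all_nodes.append(parent)
        names.append(min(names[i], names[j]))
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, : new_idx] = new_row[: new_idx]
        d[: new_idx, new_idx] = new_row[: new_idx]
        active = [a for a in active if a not in (i, j)] + [new_idx]

    # final star join of the last three clusters
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    attach(root, a, la)
    attach(root, b, lb)
    attach(root, c, lc)
    return PhyloTree(root=root)


def bootstrap_support(
    labels: list[str],
    rows: list[str],
    reps: int = 500,
    seed: int = 0,
    params: AlignParams = DEFAULT_PARAMS,
) -> PhyloTree:
    """NJ tree from aligned rows with column-resampling bootstrap supports.

    ``rows`` are equal-length aligned sequences (gaps allowed; pairwise
    deletion applies per replicate).  Supports are percentages in [0, 100]
    attached to internal edges of the full-data tree.
    """
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("aligned rows differ in length")
    if ncol < 10:
        raise ValueError("alignment too short for bootstrap")
    base = nj_tree(DistanceMatrix.from_sequences(labels, rows, aligned=True))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in rows])
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        sampled = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = nj_tree(DistanceMatrix.from_sequences(labels, sampled, aligned=True))
        except ValueError:  # a pair with no comparable position; skip replicate
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, all_leaves) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            bp = min(below, all_leaves - below, key=sorted)
            node.support = 100.0 * counts[bp] / reps
        return below

    leaves = frozenset(base.leaf_names)
    for child, _ in base.root.children:
        annotate(child, leaves)
    return base
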