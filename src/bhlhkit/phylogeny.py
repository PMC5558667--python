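"""p-distance matrices, neighbor-joining trees, bootstrap support and
subfamily extraction.

Trees are stored rooted at the final (trifurcating) NJ join but represent
unrooted topologies; supports live on internal nodes and correspond to the
bipartition induced by the node's leaf set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GAP_CHARS = frozenset("-.")


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing sites among columns where neither sequence
    has a gap (pairwise deletion)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    diffs = total = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        total += 1
        if x != y:
            diffs += 1
    if total == 0:
        raise ValueError("no comparable (gap-free) columns")
    return diffs / total


def poisson_distance(aligned_a: str, aligned_b: str) -> float:
    """Poisson-corrected protein distance: -ln(1 - p)."""
    p = p_distance(aligned_a, aligned_b)
    if p >= 1.0:
        raise ValueError("p-distance saturated")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_alignment(
        cls, alignment: Sequence[tuple[str, str]], model: str = "p"
    ) -> "DistanceMatrix":
        dist = p_distance if model == "p" else poisson_distance
        labels = [name for name, _ in alignment]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dist(alignment[i][1], alignment[j][1])
        return cls(labels, d)


@dataclass
class Node:
    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def preorder(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()


PhyloTree = Node


def nj_tree(dm: DistanceMatrix) -> Node:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the lexicographically smallest (cluster key)
    pair, where a cluster's key is its smallest leaf label. Negative branch
    lengths are reported as computed, with a warning.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [Node(name=l) for l in dm.labels]
    keys = list(dm.labels)  # sort key per active cluster
    d = dm.d.copy()
    active = list(range(n0))
    negative = False

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            negative = True
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        # reuse slot i for the merged cluster
        new_d = np.append(d, np.zeros((1, d.shape[1])), axis=0)
        new_d = np.append(new_d, np.zeros((new_d.shape[0], 1)), axis=1)
        k = new_d.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            new_d[k, m] = new_d[m, k] = (d[i, m] + d[j, m] - d[i, j]) / 2
        d = new_d
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [m for m in active if m not in (i, j)] + [k]

    if len(active) == 3:
        i, j, k = active
        nodes[i].length = (d[i, j] + d[i, k] - d[j, k]) / 2
        nodes[j].length = (d[i, j] + d[j, k] - d[i, k]) / 2
        nodes[k].length = (d[i, k] + d[j, k] - d[i, j]) / 2
        if min(nodes[i].length, nodes[j].length, nodes[k].length) < 0:
            negative = True
        order = sorted(active, key=lambda m: keys[m])
        root = Node(children=[nodes[m] for m in order])
    else:  # exactly 2 left (possible when n0 == 3 is skipped; kept for safety)
        i, j = active
        nodes[i].length = d[i, j] / 2
        nodes[j].length = d[i, j] / 2
        root = Node(children=[nodes[i], nodes[j]])

    if negative:
        warnings.warn("neighbor joining produced negative branch length(s)")
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side NOT containing
    the lexicographically smallest leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            parts.add(side)
    return parts


def bootstrap_support(
    alignment: Sequence[tuple[str, str]],
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> Node:
    """NJ tree from the full alignment with bootstrap supports (percent of
    column-resampled replicates containing each internal bipartition)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_cols = len(alignment[0][1])
    if n_cols < 1:
        raise ValueError("alignment must have at least one column")
    tree = nj_tree(DistanceMatrix.from_alignment(alignment, model))
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    names = [name for name, _ in alignment]
    cols = [[seq[c] for _, seq in alignment] for c in range(n_cols)]
    for _ in range(n_reps):
        sampled = rng.integers(0, n_cols, size=n_cols)
        rep_seqs = ["".join(cols[c][i] for c in sampled) for i in range(len(names))]
        rep_aln = list(zip(names, rep_seqs))
        try:
            rep_tree = nj_tree(DistanceMatrix.from_alignment(rep_aln, model))
        except ValueError:  # e.g. all-gap resample for some pair
            continue
        rep_parts = bipartitions(rep_tree)
        for b in counts:
            if b in rep_parts:
                counts[b] += 1

    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        canon = all_leaves - side if ref in side else side
        if 1 < len(canon) < len(all_leaves) - 1:
            node.support = 100.0 * counts.get(canon, 0) / n_reps
    return tree


def to_newick(tree: Node) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        sup = f"{int(round(node.support))}" if node.support is not None else ""
        return f"({inner}){sup}:{node.length:.6f}"

    inner = ",".join(fmt(c) for c in tree.children)
    sup = f"{int(round(tree.support))}" if tree.support is not None else ""
    return f"({inner}){sup};"


@dataclass
class SubfamilyPartition:
    assignments: dict[str, str]
    unassigned: list[str]


def extract_subfamilies(tree: Node, min_support: float = 50.0) -> SubfamilyPartition:
    """Maximal clades with support strictly greater than `min_support` become
    subfamilies, numbered in preorder; leaves outside any such clade are
    unassigned."""
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    counter = 0

    def walk(node: Node) -> None:
        nonlocal counter
        if node.is_leaf:
            unassigned.append(node.name)
            return
        if node is not tree and node.support is not None and node.support > min_support:
            counter += 1
            label = str(counter)
            for leaf in node.leaves():
                assignments[leaf.name] = label
            return
        for c in node.children:
            walk(c)

    walk(tree)
    return SubfamilyPartition(assignments, sorted(unassigned))
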