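"""UPGMA and neighbour-joining tree construction, and Newick output.

UPGMA (Sokal–Michener average linkage, size-weighted) produces a rooted
ultrametric tree under a molecular-clock assumption; neighbour joining
(Saitou–Nei) produces an unrooted tree, encoded here with a trifurcating
root, and reconstructs additive matrices exactly.  Branch lengths are
reported as computed — NJ can yield negative lengths, which are not
clamped.

Tree construction requires at least four genomes; distance matrices for
fewer genomes are still computable and exportable, just not tree-buildable.

Tie-breaking when several pairs minimise the join criterion is
deterministic: the pair (i, j) with the smallest i, then smallest j, in the
current cluster ordering is joined, and the merged cluster takes position i.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .distance import DistanceMatrix
from .errors import SizeError, ValidationError

__all__ = ["TreeNode", "upgma", "neighbor_joining", "to_newick",
           "leaf_distance_matrix", "bipartitions"]

MIN_TAXA_FOR_TREE = 4


@dataclass
class TreeNode:
    """Recursive tree node: a labelled leaf or an internal node.

    ``children`` holds ``(child, branch_length)`` pairs in construction
    order.  ``height`` is the node-to-leaf distance for UPGMA trees (leaves
    have height 0); it is meaningless for NJ trees.
    """

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child, _ in self.children:
                yield from child.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


def _validate_matrix(m: DistanceMatrix, min_taxa: int = MIN_TAXA_FOR_TREE) -> np.ndarray:
    d = np.asarray(m.values, dtype=float)
    n = len(m.samples)
    if n < min_taxa:
        raise SizeError(
            f"tree construction requires genotype data from at least "
            f"{min_taxa} genomes, got {n}"
        )
    if len(set(m.samples)) != n:
        raise ValidationError("duplicate sample names in distance matrix")
    if not np.allclose(d, d.T, rtol=1e-9, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distance matrix diagonal is not zero")
    if (d < 0).any():
        raise ValidationError("distance matrix has a negative entry")
    return d.copy()


def _argmin_pair(w: np.ndarray) -> tuple[int, int]:
    """Smallest (i, j), i < j, minimising w — ties broken by lowest i then j."""
    k = w.shape[0]
    best = None
    bi = bj = -1
    for i in range(k - 1):
        row = w[i, i + 1:]
        j = int(np.argmin(row))  # first minimum → smallest j for this i
        v = row[j]
        if best is None or v < best:
            best = v
            bi, bj = i, i + 1 + j
    return bi, bj


def upgma(m: DistanceMatrix) -> TreeNode:
    """Rooted binary UPGMA tree (size-weighted average linkage).

    Joins the closest pair at height d/2; cluster-to-cluster distances are
    arithmetic means over all leaf pairs (weighted by cluster sizes); the
    branch to a child is the parent height minus the child height.
    """
    d = _validate_matrix(m)
    nodes = [TreeNode(label=s) for s in m.samples]
    sizes = [1] * len(nodes)
    while len(nodes) > 1:
        i, j = _argmin_pair(d)
        h = d[i, j] / 2.0
        ni, nj = nodes[i], nodes[j]
        parent = TreeNode(
            children=[(ni, h - ni.height), (nj, h - nj.height)], height=h
        )
        si, sj = sizes[i], sizes[j]
        new_row = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        # merged cluster takes position i; row j removed
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [k for k in range(len(nodes)) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        sizes[i] = si + sj
        del nodes[j], sizes[j]
    return nodes[0]


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Unrooted Saitou–Nei neighbour-joining tree with a trifurcating root.

    Iteratively joins the pair minimising
    Q(i,j) = (k-2)·d(i,j) - r_i - r_j (r = row sums), with the classical
    branch-length formulas; the final three lineages join at the
    trifurcating root.  Negative branch lengths are kept as computed.
    """
    d = _validate_matrix(m)
    nodes = [TreeNode(label=s) for s in m.samples]
    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        i, j = _argmin_pair(q)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [t for t in range(k) if t != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
    # final 3-way join: branch from each remaining lineage to the root
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    return TreeNode(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])


_NEWICK_RESERVED = set(" \t\n()[]':;,")


def _newick_label(label: str) -> str:
    if label and not (_NEWICK_RESERVED & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(t: TreeNode, precision: int = 6) -> str:
    """Serialise a tree to Newick text, children in construction order.

    Branch lengths are fixed-point with ``precision`` decimals; labels
    containing whitespace or Newick-reserved characters are single-quoted.
    """

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.label or "")
        inner = ",".join(
            f"{render(child)}:{bl:.{precision}f}" for child, bl in node.children
        )
        return f"({inner})"

    return render(t) + ";"


def leaf_distance_matrix(root: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (labels in leaf order)."""
    labels = root.leaf_labels()
    index = {label: i for i, label in enumerate(labels)}
    if len(index) != len(labels):
        raise ValidationError("duplicate leaf labels")
    d = np.zeros((len(labels), len(labels)))

    def depths(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {index[node.label]: 0.0}
        maps = []
        for child, bl in node.children:
            maps.append({k: v + bl for k, v in depths(child).items()})
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for i, di in maps[a].items():
                    for j, dj in maps[b].items():
                        d[i, j] = d[j, i] = di + dj
        merged: dict[int, float] = {}
        for mp in maps:
            merged.update(mp)
        return merged

    depths(root)
    return DistanceMatrix(labels, d)


def bipartitions(root: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as its smaller leaf side.

    Two trees (rooted or not) have the same unrooted topology iff their
    bipartition sets are equal.  Sides of size 1 or n-1 are trivial and
    omitted; an exactly-half side is canonicalised to the lexicographically
    smaller one.
    """
    all_leaves = frozenset(root.leaf_labels())
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()

    def collect(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        side = frozenset().union(*(collect(c) for c, _ in node.children))
        comp = all_leaves - side
        if 1 < len(side) < n - 1:
            if len(side) < len(comp):
                splits.add(side)
            elif len(comp) < len(side):
                splits.add(comp)
            else:
                splits.add(min(side, comp, key=lambda s: tuple(sorted(s))))
        return side

    collect(root)
    return splits
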