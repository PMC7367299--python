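"""Tree-set input, majority-rule consensus, and patristic distance matrices.

Trees are represented as :class:`dendropy.Tree` objects and tree sets as
:class:`dendropy.TreeList`; this module adds the operations the comparative
pipeline needs on top of them: reading a Newick tree set with per-record
error reporting, summarising a tree set into a majority-rule consensus tree
(clades retained when present in strictly more than a threshold fraction of
the input trees, branch lengths averaged over the trees supporting each
clade), and computing the matrix of patristic (path-length) distances among
tips of a single tree.

Trees are treated as rooted, as parsed: a "clade" is the set of tip labels
descending from an internal node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "TreeSetError",
    "MissingBranchLengthError",
    "Bipartition",
    "DistanceMatrix",
    "read_newick_trees",
    "write_newick",
    "tip_label_set",
    "bipartition_frequencies",
    "majority_rule_consensus",
    "patristic_distance_matrix",
]


class NewickParseError(ValueError):
    """A Newick record could not be parsed or violates tree invariants."""


class TreeSetError(ValueError):
    """A tree-set level invariant is violated (empty set, mismatched tips)."""


class MissingBranchLengthError(ValueError):
    """A branch length required for a distance computation is absent."""


@dataclass(frozen=True)
class Bipartition:
    """A clade (tip subset) with its support across a tree set.

    Attributes
    ----------
    clade : frozenset of str
        Tip labels descending from the clade's node.
    frequency : float
        Fraction of trees in the set that contain the clade (0 < f <= 1).
    mean_branch_length : float or None
        Mean length of the subtending branch over the trees containing the
        clade, or None if no supporting tree carries a length on it.
    """

    clade: frozenset
    frequency: float
    mean_branch_length: float | None


@dataclass
class DistanceMatrix:
    """Symmetric matrix of patristic distances among tips.

    ``values[i, j]`` is the sum of branch lengths on the unique path between
    ``labels[i]`` and ``labels[j]``, in the same units as the branch lengths.
    """

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("tip labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(
            self.values[self.labels.index(i), self.labels.index(j)]
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _split_newick_records(text: str) -> list:
    """Split a Newick file into ';'-terminated records, dropping blanks."""
    records = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            records.append(chunk + ";")
    return records


def tip_label_set(tree: dendropy.Tree) -> frozenset:
    """The set of tip (leaf) labels of a tree."""
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def read_newick_trees(path) -> dendropy.TreeList:
    """Read a file of Newick records into a tree set.

    One tree per ``;``-terminated record. All trees must share an identical
    tip-label set; tip labels must be unique within a tree.

    Raises
    ------
    NewickParseError
        If a record is malformed or contains duplicate tips, naming the
        offending record (1-based).
    TreeSetError
        If the file contains no trees or the trees' tip sets differ.
    """
    text = Path(path).read_text()
    records = _split_newick_records(text)
    if not records:
        raise TreeSetError(f"no Newick records found in {path}")
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=tns)
    for k, rec in enumerate(records, start=1):
        try:
            tree = dendropy.Tree.get(
                data=rec, schema="newick", taxon_namespace=tns
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"record {k}: {exc}") from exc
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise NewickParseError(f"record {k}: duplicate tip labels {dupes}")
        trees.append(tree)
    _validate_tree_set(trees)
    return trees


def _validate_tree_set(trees: Sequence[dendropy.Tree]) -> frozenset:
    if len(trees) == 0:
        raise TreeSetError("tree set is empty")
    ref = tip_label_set(trees[0])
    for k, tree in enumerate(trees[1:], start=2):
        tips = tip_label_set(tree)
        if tips != ref:
            missing = sorted(ref - tips)
            extra = sorted(tips - ref)
            raise TreeSetError(
                f"record {k}: tip set differs from record 1 "
                f"(missing {missing}, extra {extra})"
            )
    return ref


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a single tree as a Newick record."""
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Majority-rule consensus
# ---------------------------------------------------------------------------

def bipartition_frequencies(trees: Sequence[dendropy.Tree]) -> list:
    """Count every non-trivial clade across a tree set.

    Returns one :class:`Bipartition` per clade observed in at least one
    tree, with its frequency and the mean subtending branch length over the
    trees containing it. Trivial clades (single tips and the full tip set)
    are excluded.
    """
    tips = _validate_tree_set(trees)
    n_tips = len(tips)
    counts: dict = {}
    for tree in trees:
        seen = set()
        for node in tree.postorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(clade) <= 1 or len(clade) >= n_tips:
                continue
            if clade in seen:  # unifurcations could repeat a clade
                continue
            seen.add(clade)
            cnt, bl_sum, bl_n = counts.get(clade, (0, 0.0, 0))
            length = node.edge.length
            if length is not None:
                bl_sum += length
                bl_n += 1
            counts[clade] = (cnt + 1, bl_sum, bl_n)
    n_trees = len(trees)
    out = []
    for clade, (cnt, bl_sum, bl_n) in counts.items():
        out.append(
            Bipartition(
                clade=clade,
                frequency=cnt / n_trees,
                mean_branch_length=(bl_sum / bl_n) if bl_n else None,
            )
        )
    out.sort(key=lambda b: (-len(b.clade), sorted(b.clade)))
    return out


def _mean_tip_branch_lengths(trees: Sequence[dendropy.Tree]) -> Mapping:
    sums: dict = {}
    for tree in trees:
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if leaf.edge.length is not None:
                s, n = sums.get(label, (0.0, 0))
                sums[label] = (s + leaf.edge.length, n + 1)
    return {lab: s / n for lab, (s, n) in sums.items()}


def majority_rule_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus of a tree set.

    The output contains exactly the non-trivial clades whose frequency in
    the set is *strictly greater* than ``threshold``; for threshold >= 0.5
    these are mutually compatible by construction (any two retained clades
    co-occur in at least one input tree). Consensus branch lengths are the
    arithmetic mean over the trees containing the clade; tip branch lengths
    are averaged over all trees. Regions with no majority clade collapse to
    polytomies.

    Parameters
    ----------
    trees :
        Non-empty sequence of trees over an identical tip set.
    threshold :
        Clade-retention threshold as a fraction, 0.5 <= threshold < 1.
    """
    if not 0.5 <= threshold < 1:
        raise ValueError(f"threshold must be in [0.5, 1), got {threshold}")
    tips = sorted(_validate_tree_set(trees))
    biparts = bipartition_frequencies(trees)
    retained = [b for b in biparts if b.frequency > threshold]
    # Nest clades: insert in decreasing size so a clade's parent (smallest
    # strict superset) is always already in place.
    retained.sort(key=lambda b: (-len(b.clade), sorted(b.clade)))

    tns = dendropy.TaxonNamespace(tips)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    placed: list = [(frozenset(tips), root)]
    for b in retained:
        parent = None
        for clade, node in placed:
            if b.clade < clade and (parent is None or len(clade) < len(parent[0])):
                parent = (clade, node)
        assert parent is not None  # root is a superset of everything
        child = parent[1].new_child(edge_length=b.mean_branch_length)
        placed.append((b.clade, child))
    tip_bl = _mean_tip_branch_lengths(trees)
    for label in tips:
        parent = min(
            ((clade, node) for clade, node in placed if label in clade),
            key=lambda cn: len(cn[0]),
        )
        leaf = parent[1].new_child(edge_length=tip_bl.get(label))
        leaf.taxon = tns.get_taxon(label)
    return tree


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Matrix of path-length (patristic) distances among the tips of a tree.

    Entry (i, j) is the sum of branch lengths along the unique path between
    tips i and j: depth(i) + depth(j) - 2 * depth(lca(i, j)). Tip labels are
    returned in sorted order so the matrix is independent of the tree's
    internal node ordering.

    Raises
    ------
    MissingBranchLengthError
        If any non-root branch lacks a length, naming the node.
    """
    labels = sorted(tip_label_set(tree))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    root = tree.seed_node
    depth: dict = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            desc = node.taxon.label if node.taxon else (
                "internal node over tips "
                + repr(sorted(lf.taxon.label for lf in node.leaf_iter())[:3])
            )
            raise MissingBranchLengthError(f"missing branch length at {desc}")
        if node.edge.length < 0:
            raise ValueError("branch lengths must be nonnegative")
        depth[node] = depth[node.parent_node] + node.edge.length

    leaf_depth = np.zeros(n)
    D = np.zeros((n, n))
    # leaf index lists per node, built bottom-up; cross-child pairs have
    # their LCA at the current node
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leaf_depth[i] = depth[node]
            below[node] = [i]
            continue
        groups = [below.pop(ch) for ch in node.child_nodes()]
        merged: list = []
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                a = np.asarray(groups[gi])
                b = np.asarray(groups[gj])
                d = (
                    leaf_depth[a][:, None]
                    + leaf_depth[b][None, :]
                    - 2.0 * depth[node]
                )
                D[a[:, None], b[None, :]] = d
                D[b[:, None], a[None, :]] = d.T
            merged.extend(groups[gi])
        below[node] = merged
    return DistanceMatrix(labels=labels, values=D)
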