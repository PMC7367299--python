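"""Shared fixtures and independent test oracles.

The oracles here are deliberately naive re-implementations (direct path
walks, explicit subset enumeration, plain mean/SSE arithmetic) so they
stay independent of the vectorised library code they check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from phylobrt.trait_table import CONTINUOUS, NOMINAL, ModelFrame


# ---------------------------------------------------------------------------
# Tree oracles
# ---------------------------------------------------------------------------

def naive_patristic(tree: dendropy.Tree) -> dict:
    """Per-pair patristic distances by explicit upward path walks."""
    leaves = list(tree.leaf_node_iter())

    def ancestors(leaf):
        out = {}
        d = 0.0
        node = leaf
        while node is not None:
            out[id(node)] = d
            if node.edge.length is not None:
                d += node.edge.length
            node = node.parent_node
        return out

    dists = {}
    for a, b in itertools.combinations(leaves, 2):
        anc_a = ancestors(a)
        d = 0.0
        node = b
        while id(node) not in anc_a:
            d += node.edge.length or 0.0
            node = node.parent_node
        total = d + anc_a[id(node)]
        dists[frozenset((a.taxon.label, b.taxon.label))] = total
    return dists


def clade_counts(trees) -> dict:
    """Brute-force count of non-trivial clades, with branch-length sums."""
    n_tips = len(list(trees[0].leaf_node_iter()))
    counts: dict = {}
    for tree in trees:
        for node in tree.preorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(clade) <= 1 or len(clade) >= n_tips:
                continue
            cnt, bl, bn = counts.get(clade, (0, 0.0, 0))
            if node.edge.length is not None:
                bl += node.edge.length
                bn += 1
            counts[clade] = (cnt + 1, bl, bn)
    return counts


def tree_clades(tree) -> set:
    """The set of non-trivial clades of one tree."""
    n_tips = len(list(tree.leaf_node_iter()))
    out = set()
    for node in tree.preorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < n_tips:
            out.add(clade)
    return out


# ---------------------------------------------------------------------------
# Tree-fit oracle: naive greedy best-first splitting
# ---------------------------------------------------------------------------

def _naive_sse(r):
    return float(np.sum((r - r.mean()) ** 2)) if r.size else 0.0


def _naive_column_splits(v, kind, n_lev):
    """Enumerate every candidate split of one column's present values."""
    if kind == NOMINAL:
        present = sorted(set(int(x) for x in v))
        if len(present) < 2:
            return
        rest = present[1:]
        for r_size in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r_size):
                left = {present[0], *combo}
                if len(left) == len(present):
                    continue
                yield None, left
    else:
        sv = np.unique(v)
        for a, b in zip(sv[:-1], sv[1:]):
            yield 0.5 * (a + b), None


def naive_best_split(X, kinds, n_levels, r, idx):
    best = None
    for j in range(X.shape[1]):
        v = X[idx, j]
        pres = ~np.isnan(v)
        vv, rr = v[pres], r[idx][pres]
        if vv.size < 2:
            continue
        for thr, left in _naive_column_splits(vv, kinds[j], n_levels[j]):
            mask = np.isin(vv, list(left)) if left is not None else vv <= thr
            if mask.all() or not mask.any():
                continue
            imp = _naive_sse(rr) - _naive_sse(rr[mask]) - _naive_sse(rr[~mask])
            if best is None or imp > best[0] + 1e-12:
                best = (imp, j, thr, left)
    return best


def naive_fit_tree_total_improvement(X, kinds, n_levels, r, max_splits):
    """Total improvement of naive greedy best-first growth."""
    leaves = [np.arange(X.shape[0])]
    total = 0.0
    for _ in range(max_splits):
        best = None
        for pos, rows in enumerate(leaves):
            cand = naive_best_split(X, kinds, n_levels, r, rows)
            if cand is None:
                continue
            if best is None or cand[0] > best[0][0] + 1e-12:
                best = (cand, pos)
        if best is None or best[0][0] <= 1e-12:
            break
        (imp, j, thr, left), pos = best
        rows = leaves.pop(pos)
        v = X[rows, j]
        miss = np.isnan(v)
        mask = np.isin(v, list(left)) if left is not None else v <= thr
        mask = mask & ~miss
        other = ~mask & ~miss
        if mask.sum() >= other.sum():
            mask |= miss
        else:
            other |= miss
        leaves.append(rows[mask])
        leaves.append(rows[other])
        total += imp
    return total


# ---------------------------------------------------------------------------
# Frame helpers
# ---------------------------------------------------------------------------

def make_frame(X, kinds=None, levels=None, groups=None) -> ModelFrame:
    """Wrap a raw matrix in a ModelFrame with minimal metadata."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    kinds = [CONTINUOUS] * p if kinds is None else kinds
    columns = [f"x{j}" for j in range(p)]
    lev = {}
    if levels:
        for j, lv in levels.items():
            lev[columns[j]] = lv
    return ModelFrame(
        X=X,
        columns=columns,
        kinds=kinds,
        levels=lev,
        groups=["trait"] * p if groups is None else groups,
        species=[f"s{i}" for i in range(X.shape[0])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
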