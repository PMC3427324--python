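"""Distance-based tree inference with nonparametric bootstrap support.

A deterministic desk-scale stand-in for heavyweight ML/Bayesian tree
engines: Jukes-Cantor corrected distances from pairwise-deletion
p-distances, canonical neighbor-joining (Q-matrix ties broken by the
lexicographically smallest taxon pair, negative branch lengths clamped to
zero with the deficit moved to the sister edge), and clade support from
column resampling with replacement (with an optional codon-triple
resampling mode that preserves codon phase).  The exact matrices and
partition files for external ML engines are exported by ``io_formats``;
this module only has to demonstrate topology recovery.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("opilio")


# ---------------------------------------------------------------------------
# distances

def jc_distance(p: float, ceiling: float = 5.0) -> tuple[float, bool]:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).

    Returns (distance, saturated); p >= 0.75 saturates and is set to the
    ceiling with a logged warning.
    """
    if p < 0:
        raise ValueError("p-distance must be nonnegative")
    if p >= 0.75:
        logger.warning("p-distance %.3f saturated; using ceiling %.2f", p, ceiling)
        return ceiling, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean mask, same shape

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape disagrees with taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite and nonnegative")
        if self.saturated is None:
            self.saturated = np.zeros_like(m, dtype=bool)


_NT = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_rows(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = sorted(rows)
    L = len(next(iter(rows.values())))
    enc = np.full((len(taxa), L), -1, dtype=np.int8)
    for i, t in enumerate(taxa):
        enc[i] = [_NT.get(c, -1) for c in rows[t]]
    return taxa, enc


def distance_matrix(rows: dict[str, str], ceiling: float = 5.0) -> DistanceMatrix:
    """JC-corrected distances from pairwise-deletion p-distances."""
    taxa, enc = _encode_rows(rows)
    n = len(taxa)
    D = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            comp = (enc[i] >= 0) & (enc[j] >= 0)
            nc = int(comp.sum())
            p = float(((enc[i] != enc[j]) & comp).sum() / nc) if nc else 0.0
            d, s = jc_distance(p, ceiling)
            D[i, j] = D[j, i] = d
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(taxa, D, sat)


# ---------------------------------------------------------------------------
# trees as nested tuples + splits

@dataclass
class TreeNode:
    """Unrooted tree node (rooted data structure, unrooted semantics)."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        def fmt(nd: TreeNode) -> str:
            if not nd.children:
                return f"{nd.label}:{nd.length:.10g}"
            inner = ",".join(fmt(c) for c in sorted(
                nd.children, key=lambda x: min(x.leaves())))
            lab = ""
            if with_support and nd.support is not None:
                lab = f"{nd.support:.0f}"
            return f"({inner}){lab}:{nd.length:.10g}"
        inner = ",".join(fmt(c) for c in sorted(
            self.children, key=lambda x: min(x.leaves())))
        return f"({inner});"


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each as the side not holding the smallest leaf."""
    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(nd: TreeNode) -> frozenset[str]:
        if not nd.children:
            return frozenset([nd.label])
        below = frozenset().union(*(walk(c) for c in nd.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            out.add(side)
        return below

    walk(tree)
    return out


def rf_distance(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Robinson-Foulds: splits present in exactly one of the two trees."""
    la, lb = frozenset(tree_a.leaves()), frozenset(tree_b.leaves())
    if la != lb:
        raise ValueError("leaf sets differ")
    return len(splits(tree_a) ^ splits(tree_b))


def tree_from_newick(text: str) -> TreeNode:
    """Minimal Newick reader for trees produced by :meth:`TreeNode.newick`."""
    import dendropy
    dt = dendropy.Tree.get(data=text, schema="newick")

    def conv(nd) -> TreeNode:
        t = TreeNode(label=nd.taxon.label if nd.taxon else None,
                     length=nd.edge.length or 0.0)
        t.children = [conv(c) for c in nd.child_nodes()]
        return t

    return conv(dt.seed_node)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining.

    Ties in the Q matrix are broken by the lexicographically smallest
    (cluster, cluster) taxon-label pair, where a cluster is named by its
    smallest leaf.  Negative branch lengths are clamped to zero and the
    deficit moved to the sister edge, preserving path lengths.
    """
    n = len(dm.taxa)
    if n < 4:
        logger.warning("NJ with %d taxa: returning trivial tree", n)
        root = TreeNode()
        root.children = [TreeNode(label=t, length=float(dm.matrix[0, i]) if i else 0.0)
                         for i, t in enumerate(dm.taxa)]
        return root

    nodes: dict[int, TreeNode] = {i: TreeNode(label=t)
                                  for i, t in enumerate(dm.taxa)}
    names: dict[int, str] = {i: t for i, t in enumerate(dm.taxa)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.matrix[i, j])

    def dist(i: int, j: int) -> float:
        return D[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best: tuple[float, str, str, int, int] | None = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                a, b = sorted((names[i], names[j]))
                key = (q, a, b)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (q, a, b, i, j)
        _, _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        nodes[next_id] = parent
        names[next_id] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, next_id), max(k, next_id))] = \
                0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = TreeNode()
    for idx, L in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(L, 0.0)
        root.children.append(nodes[idx])
    root.children.sort(key=lambda c: min(c.leaves()))
    return root


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class SupportTree:
    tree: TreeNode
    supports: dict[frozenset[str], float]      # split -> bootstrap percentage
    replicates: int

    def clade_support(self, clade: frozenset[str]) -> float | None:
        """Support for a leaf set, looked up on either side of the split."""
        all_leaves = frozenset(self.tree.leaves())
        ref = min(all_leaves)
        side = clade if ref not in clade else all_leaves - clade
        return self.supports.get(frozenset(side))


def _pair_diff_arrays(rows: dict[str, str]) -> tuple[list[str], list, np.ndarray,
                                                     np.ndarray]:
    taxa, enc = _encode_rows(rows)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    L = enc.shape[1]
    diff = np.zeros((len(pairs), L), dtype=np.float64)
    comp = np.zeros((len(pairs), L), dtype=np.float64)
    for idx, (i, j) in enumerate(pairs):
        c = (enc[i] >= 0) & (enc[j] >= 0)
        comp[idx] = c
        diff[idx] = (enc[i] != enc[j]) & c
    return taxa, pairs, diff, comp


def _tree_from_pair_p(taxa: list[str], pairs: list, p: np.ndarray,
                      ceiling: float) -> TreeNode:
    n = len(taxa)
    D = np.zeros((n, n))
    for idx, (i, j) in enumerate(pairs):
        d, _ = jc_distance(float(p[idx]), ceiling)
        D[i, j] = D[j, i] = d
    return nj_tree(DistanceMatrix(taxa, D))


def bootstrap_support(rows: dict[str, str], replicates: int = 500,
                      seed: int = 0, codon_triples: bool = False,
                      ceiling: float = 5.0) -> SupportTree:
    """NJ tree with nonparametric bootstrap support percentages.

    Columns (or codon triples, preserving codon phase) are resampled with
    replacement; support for each internal split of the full-data tree is
    the percentage of replicate trees containing it.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    taxa, pairs, diff, comp = _pair_diff_arrays(rows)
    L = diff.shape[1]
    rng = np.random.default_rng(seed)

    p_full = diff.sum(axis=1) / np.maximum(comp.sum(axis=1), 1.0)
    tree = _tree_from_pair_p(taxa, pairs, p_full, ceiling)
    target = splits(tree)
    counts = {s: 0 for s in target}

    if codon_triples:
        if L % 3:
            raise ValueError("codon resampling needs length divisible by 3")
        n_units = L // 3
        diff_u = diff.reshape(len(pairs), n_units, 3).sum(axis=2)
        comp_u = comp.reshape(len(pairs), n_units, 3).sum(axis=2)
    else:
        n_units = L
        diff_u, comp_u = diff, comp

    for _ in range(replicates):
        w = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units)).astype(float)
        d = diff_u @ w
        c = comp_u @ w
        p = d / np.maximum(c, 1.0)
        rep = _tree_from_pair_p(taxa, pairs, p, ceiling)
        for s in splits(rep):
            if s in counts:
                counts[s] += 1

    supports = {s: 100.0 * c / replicates for s, c in counts.items()}

    def annotate(nd: TreeNode, all_leaves: frozenset[str], ref: str) -> frozenset[str]:
        if not nd.children:
            return frozenset([nd.label])
        below = frozenset().union(*(annotate(c, all_leaves, ref)
                                    for c in nd.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            nd.support = supports.get(side)
        return below

    allv = frozenset(tree.leaves())
    annotate(tree, allv, min(allv))
    return SupportTree(tree, supports, replicates)
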