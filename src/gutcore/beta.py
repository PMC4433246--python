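"""Beta diversity: binary Jaccard, UniFrac (both flavours), Manhattan
distance on transformed abundances, distance summary statistics, and
jackknifed UPGMA clustering with bipartition support.

UniFrac is computed by an explicit edge walk: for every branch of the
rooted tree we know the fraction of each sample's reads (or, unweighted,
the mere presence) below it, and the distance is assembled from the
per-branch contrasts.  Unweighted UniFrac is unique branch length over
branch length covered by either sample; weighted UniFrac is the
abundance-weighted branch-length difference, normalized by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats as sps
from skbio import DistanceMatrix, TreeNode

from .preprocess import rarefy
from .table import OtuTable


def binary_jaccard(table: OtuTable) -> DistanceMatrix:
    """1 - |A n B| / |A u B| on presence/absence rows."""
    pres = table.presence().to_numpy()
    n = pres.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(pres[i], pres[j]).sum()
            inter = np.logical_and(pres[i], pres[j]).sum()
            d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - inter / union
    return DistanceMatrix(d, ids=table.sample_ids)


def manhattan_distance(frame: pd.DataFrame) -> DistanceMatrix:
    """Sum of absolute coordinate differences between rows.

    On raw fractional rows this equals twice the Bray-Curtis
    dissimilarity; here it is typically applied to arcsine-transformed
    relative abundances.
    """
    arr = frame.to_numpy(dtype=float)
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(arr - arr[i]).sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(frame.index))


# ---------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------

def _edge_structure(tree: TreeNode, otu_ids: list[str]):
    """Branch lengths and, per branch, the table-OTU indices below it.

    Tree tips absent from the table simply contribute nothing; table
    OTUs absent from the tree are an error.
    """
    col = {o: k for k, o in enumerate(otu_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tip_names)
    if missing:
        raise ValueError(f"table OTUs absent from tree: {missing}")
    lengths: list[float] = []
    members: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            idx = np.array([col[node.name]] if node.name in col else [], dtype=int)
        else:
            parts = [below[id(c)] for c in node.children]
            idx = np.concatenate(parts) if parts else np.array([], dtype=int)
        below[id(node)] = idx
        if node.parent is not None and node.length:
            lengths.append(float(node.length))
            members.append(idx)
    return np.asarray(lengths), members


def _branch_matrix(table: OtuTable, tree: TreeNode):
    """(branch lengths, samples x branches matrix of read counts below each branch)."""
    lengths, members = _edge_structure(tree, table.otu_ids)
    counts = table.counts()
    mat = np.zeros((counts.shape[0], len(lengths)))
    for e, idx in enumerate(members):
        if idx.size:
            mat[:, e] = counts[:, idx].sum(axis=1)
    return lengths, mat


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    lengths, mat = _branch_matrix(table, tree)
    pres = mat > 0
    n = pres.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = np.logical_or(pres[i], pres[j])
            both = np.logical_and(pres[i], pres[j])
            union = lengths[either].sum()
            shared = lengths[both].sum()
            d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - shared / union
    return DistanceMatrix(d, ids=table.sample_ids)


def weighted_unifrac(
    table: OtuTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    lengths, mat = _branch_matrix(table, tree)
    totals = table.sample_sums().to_numpy().astype(float)
    if (totals == 0).any():
        raise ValueError("weighted UniFrac is undefined for empty samples")
    frac = mat / totals[:, None]
    n = frac.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = (lengths * np.abs(frac[i] - frac[j])).sum()
            if normalized:
                den = (lengths * (frac[i] + frac[j])).sum()
                val = 0.0 if den == 0 else num / den
            else:
                val = num
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------
# Distance summaries and boxplot comparisons
# ---------------------------------------------------------------------

def _pair_category(gi: str, gj: str) -> str:
    if gi == gj:
        return f"within {gi}"
    a, b = sorted([gi, gj])
    return f"{a} vs {b}"


def distance_group_stats(dm: DistanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """Mean and SD of distances per group pair (within and between).

    A group with a single member has no within-group distances; its row
    is kept with NaNs and ``n_pairs`` 0 so the gap is explicit.
    """
    labels = groups.loc[list(dm.ids)]
    values: dict[str, list[float]] = {}
    ids = list(dm.ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cat = _pair_category(labels.iloc[i], labels.iloc[j])
            values.setdefault(cat, []).append(dm[ids[i], ids[j]])
    for g in sorted(set(labels)):
        values.setdefault(f"within {g}", [])
    rows = []
    for cat in sorted(values):
        vals = np.asarray(values[cat])
        rows.append(
            {
                "category": cat,
                "n_pairs": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def distance_boxplot_tests(dm: DistanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """Welch two-sample t-tests between every pair of distance
    "boxplots" (within/between-group distance distributions), with
    Bonferroni correction over all comparisons performed."""
    labels = groups.loc[list(dm.ids)]
    buckets: dict[str, list[float]] = {}
    ids = list(dm.ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cat = _pair_category(labels.iloc[i], labels.iloc[j])
            buckets.setdefault(cat, []).append(dm[ids[i], ids[j]])
    cats = sorted(c for c in buckets if len(buckets[c]) >= 2)
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            x, y = buckets[cats[i]], buckets[cats[j]]
            t, p = sps.ttest_ind(x, y, equal_var=False)
            rows.append({"a": cats[i], "b": cats[j], "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows, columns=["a", "b", "t", "p"])
    k = len(out)
    out["p_bonferroni"] = (out["p"] * k).clip(upper=1.0) if k else out["p"]
    return out


# ---------------------------------------------------------------------
# UPGMA + jackknife support
# ---------------------------------------------------------------------

@dataclass
class JackknifeResult:
    tree_newick: str
    support: dict[frozenset, float]
    replicates: int

    def support_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": ";".join(sorted(k)), "support": v}
            for k, v in sorted(self.support.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["clade", "support"])


def upgma(dm: DistanceMatrix):
    """Average-linkage clustering; returns the scipy cluster-tree root."""
    z = sch.linkage(squareform(np.asarray(dm.data)), method="average")
    return sch.to_tree(z)


def _clades(root, ids: list[str]) -> set[frozenset]:
    """Non-trivial sample bipartitions (clades) of a UPGMA tree."""
    out: set[frozenset] = set()

    def walk(node) -> list[str]:
        if node.is_leaf():
            return [ids[node.id]]
        members = walk(node.left) + walk(node.right)
        if 1 < len(members) < len(ids):
            out.add(frozenset(members))
        return members

    walk(root)
    return out


def upgma_newick(root, ids: list[str]) -> str:
    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{ids[node.id]}:{parent_height:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"


def jackknife_beta(
    table: OtuTable,
    depth: int,
    replicates: int = 100,
    metric="jaccard",
    tree: TreeNode | None = None,
    seed_or_rng=0,
) -> JackknifeResult:
    """Support for each clade of the full-data UPGMA tree, estimated as
    the fraction of rarefied replicates whose UPGMA tree contains it.

    ``metric`` is "jaccard", "unweighted_unifrac" or a callable
    ``table -> DistanceMatrix``.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )

    def dist(t: OtuTable) -> DistanceMatrix:
        if callable(metric):
            return metric(t)
        if metric == "jaccard":
            return binary_jaccard(t)
        if metric == "unweighted_unifrac":
            if tree is None:
                raise ValueError("unifrac jackknife needs a tree")
            return unweighted_unifrac(t, tree)
        raise ValueError(f"unknown jackknife metric {metric!r}")

    full_dm = dist(table)
    ids = list(full_dm.ids)
    ref_root = upgma(full_dm)
    ref_clades = _clades(ref_root, ids)
    hits = {c: 0 for c in ref_clades}
    for _ in range(replicates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = rarefy(table, depth, rng)
        rep_dm = dist(rep)
        rep_clades = _clades(upgma(rep_dm), list(rep_dm.ids))
        for c in ref_clades:
            if c in rep_clades:
                hits[c] += 1
    support = {c: hits[c] / replicates for c in ref_clades}
    return JackknifeResult(upgma_newick(ref_root, ids), support, replicates)
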