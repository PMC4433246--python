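"""Indicator-value (IndVal) analysis with permutation significance and
cross-marker concordance filtering.

For taxon i and cluster j the indicator value is the product of
specificity A_ij (taxon i's mean abundance in cluster j divided by the
sum of its mean abundances over all clusters) and fidelity B_ij (the
fraction of cluster-j samples containing the taxon):

    IndVal_ij = A_ij * B_ij,   IndVal_i = max_j IndVal_ij.

An indicator value of 1 means the taxon is exclusive to one cluster
and present in every one of its samples.  By default A is computed on
per-sample relative abundances (library-size robust); raw counts are
available as the historical alternative.  Significance comes from
freely permuting the cluster labels over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import OtuTable
from .taxonomy import UNASSIGNED


@dataclass
class IndValResult:
    """Per-taxon indicator summary plus the full taxon x cluster values."""

    values: pd.DataFrame        # taxa x clusters, A*B
    specificity: pd.DataFrame   # A
    fidelity: pd.DataFrame      # B
    summary: pd.DataFrame       # taxon, cluster, indval, tie flag
    mode: str

    def max_indval(self, taxon: str) -> float:
        return float(self.summary.at[taxon, "indval"])

    def assigned_cluster(self, taxon: str) -> str | None:
        c = self.summary.at[taxon, "cluster"]
        return None if pd.isna(c) else c


def _abundance_matrix(table: OtuTable, mode: str) -> pd.DataFrame:
    if mode == "relative":
        return table.relative()
    if mode == "raw":
        return table.data.astype(float)
    raise ValueError("mode must be 'relative' or 'raw'")


def _indval_matrices(abund: np.ndarray, pres: np.ndarray, codes: np.ndarray, k: int):
    """A, B, A*B as (taxa x clusters) arrays from sample x taxon data."""
    n_taxa = abund.shape[1]
    means = np.empty((k, n_taxa))
    freqs = np.empty((k, n_taxa))
    for j in range(k):
        rows = codes == j
        means[j] = abund[rows].mean(axis=0)
        freqs[j] = pres[rows].mean(axis=0)
    totals = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(totals > 0, means / np.where(totals > 0, totals, 1.0), 0.0)
    return a.T, freqs.T, (a * freqs).T


def indval(
    table: OtuTable, clusters: pd.Series, mode: str = "relative"
) -> IndValResult:
    """Indicator values of every taxon for one clustering of samples.

    ``clusters`` maps every sample id to exactly one cluster label;
    empty clusters are an error.  Argmax ties are broken by
    lexicographic cluster name and flagged.
    """
    labels = clusters.loc[list(table.sample_ids)].astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    codes = labels.map({c: i for i, c in enumerate(names)}).to_numpy()
    abund = _abundance_matrix(table, mode).to_numpy()
    pres = (table.counts() > 0).astype(float)
    a, b, v = _indval_matrices(abund, pres, codes, len(names))
    taxa = table.otu_ids
    values = pd.DataFrame(v, index=taxa, columns=names)
    rows = []
    for t_idx, taxon in enumerate(taxa):
        row = v[t_idx]
        if row.max() <= 0:
            rows.append({"taxon": taxon, "cluster": np.nan, "indval": 0.0, "tie": False})
            continue
        best = int(np.argmax(row))  # argmax -> first = lexicographically smallest
        tie = bool((np.abs(row - row[best]) < 1e-12).sum() > 1)
        rows.append(
            {"taxon": taxon, "cluster": names[best], "indval": float(row[best]), "tie": tie}
        )
    summary = pd.DataFrame(rows).set_index("taxon")
    return IndValResult(
        values=values,
        specificity=pd.DataFrame(a, index=taxa, columns=names),
        fidelity=pd.DataFrame(b, index=taxa, columns=names),
        summary=summary,
        mode=mode,
    )


def indval_significance(
    table: OtuTable,
    clusters: pd.Series,
    permutations: int = 999,
    seed_or_rng=0,
    mode: str = "relative",
) -> pd.Series:
    """Permutation p-value per taxon for its maximum indicator value,
    under free shuffling of cluster labels over samples."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    labels = clusters.loc[list(table.sample_ids)].astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    codes = labels.map({c: i for i, c in enumerate(names)}).to_numpy()
    abund = _abundance_matrix(table, mode).to_numpy()
    pres = (table.counts() > 0).astype(float)
    k = len(names)
    _, _, v_obs = _indval_matrices(abund, pres, codes, k)
    obs_max = v_obs.max(axis=1)
    hits = np.zeros(len(table.otu_ids))
    for _ in range(permutations):
        perm = rng.permutation(codes)
        _, _, v = _indval_matrices(abund, pres, perm, k)
        hits += v.max(axis=1) >= obs_max - 1e-12
    p = (hits + 1) / (permutations + 1)
    return pd.Series(p, index=table.otu_ids, name="p_value")


def concordant_indicators(
    result_a: IndValResult,
    p_a: pd.Series,
    result_b: IndValResult,
    p_b: pd.Series,
    alpha: float = 0.05,
    min_indval: float = 0.6,
) -> pd.DataFrame:
    """Cross-marker concordance filter over two IndVal analyses.

    A taxon (matched by name; unassigned pools excluded) is retained
    when it is significant in both markers, assigned to the same
    cluster in both, and reaches ``min_indval`` in at least one marker.
    The output mirrors a side-by-side two-marker indicator table.
    """
    shared = [
        t
        for t in result_a.summary.index
        if t in set(result_b.summary.index) and t != UNASSIGNED
    ]
    rows = []
    for taxon in shared:
        ca = result_a.assigned_cluster(taxon)
        cb = result_b.assigned_cluster(taxon)
        if ca is None or cb is None or ca != cb:
            continue
        pa, pb = float(p_a[taxon]), float(p_b[taxon])
        if pa >= alpha or pb >= alpha:
            continue
        va = result_a.max_indval(taxon)
        vb = result_b.max_indval(taxon)
        if max(va, vb) < min_indval:
            continue
        rows.append(
            {
                "taxon": taxon,
                "cluster": ca,
                "indval_a": va,
                "indval_b": vb,
                "p_a": pa,
                "p_b": pb,
            }
        )
    out = pd.DataFrame(
        rows, columns=["taxon", "cluster", "indval_a", "indval_b", "p_a", "p_b"]
    )
    return out.sort_values(
        ["cluster", "taxon"], ignore_index=True
    ) if len(out) else out
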