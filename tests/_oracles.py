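"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive and separate from the package's
code paths: per-edge tree walks for UniFrac, direct evaluation of the
indicator-value definition, exhaustive enumerations for permutation
tests, and closed-form expectations for subsampling.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb

import numpy as np


# -- UniFrac by per-edge enumeration ----------------------------------

def _edges_with_tipsets(tree):
    """(length, frozenset of tip names below the edge) for every branch."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.length:
            tips = frozenset(t.name for t in ([node] if node.is_tip() else node.tips()))
            out.append((float(node.length), tips))
    return out


def naive_unweighted_unifrac(tree, present_a, present_b):
    a, b = set(present_a), set(present_b)
    union = shared = 0.0
    for length, tips in _edges_with_tipsets(tree):
        in_a = bool(tips & a)
        in_b = bool(tips & b)
        if in_a or in_b:
            union += length
        if in_a and in_b:
            shared += length
    return 0.0 if union == 0 else 1.0 - shared / union


def naive_weighted_unifrac(tree, counts_a, counts_b, normalized=True):
    """counts_* map tip name -> count; absent tips count zero."""
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    num = den = 0.0
    for length, tips in _edges_with_tipsets(tree):
        fa = sum(counts_a.get(t, 0) for t in tips) / tot_a
        fb = sum(counts_b.get(t, 0) for t in tips) / tot_b
        num += length * abs(fa - fb)
        den += length * (fa + fb)
    if not normalized:
        return num
    return 0.0 if den == 0 else num / den


# -- IndVal by direct evaluation of the definition --------------------

def brute_indval(abundance, clusters, use_relative=True):
    """taxon -> {cluster: A*B} from a samples x taxa DataFrame.

    Specificity A: mean (relative) abundance in the cluster over the
    sum of mean abundances across clusters; fidelity B: occurrence
    frequency within the cluster.
    """
    frame = abundance.astype(float)
    if use_relative:
        frame = frame.div(frame.sum(axis=1), axis=0)
    out = {}
    names = sorted(set(clusters))
    for taxon in frame.columns:
        means = {}
        freqs = {}
        for c in names:
            members = [s for s in frame.index if clusters[s] == c]
            vals = frame.loc[members, taxon]
            means[c] = vals.mean()
            freqs[c] = float((abundance.loc[members, taxon] > 0).mean())
        total = sum(means.values())
        out[taxon] = {
            c: (0.0 if total == 0 else means[c] / total) * freqs[c] for c in names
        }
    return out


# -- PERMANOVA pseudo-F and exhaustive p ------------------------------

def brute_pseudo_f(d, labels):
    d = np.asarray(d, dtype=float)
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        if len(idx) > 1:
            ss_within += sum(
                d[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def exhaustive_permanova_p(d, labels):
    """Exact permutation p over all label orderings (tiny n only)."""
    labels = list(labels)
    f_obs = brute_pseudo_f(d, labels)
    hits = total = 0
    for perm in permutations(range(len(labels))):
        f = brute_pseudo_f(d, [labels[i] for i in perm])
        hits += f >= f_obs - 1e-12
        total += 1
    return hits / total


# -- subsampling expectations -----------------------------------------

def expected_rarefied_richness(counts, depth):
    """E[# OTUs observed] after drawing `depth` reads without
    replacement: sum over OTUs of 1 - C(N - n_i, d) / C(N, d)."""
    counts = [int(c) for c in counts if c > 0]
    total = sum(counts)
    return sum(1.0 - comb(total - c, depth) / comb(total, depth) for c in counts)


def hypergeometric_mean(counts, depth):
    """E[rarefied count] per OTU = depth * n_i / N."""
    counts = np.asarray(counts, dtype=float)
    return depth * counts / counts.sum()


# -- relative core length, exhaustively over subsets ------------------

def brute_relative_core_length(presence, rows, prevalence=0.8):
    """presence: bool array samples x OTUs; rows: indices of the chosen
    individuals.  Ceiling prevalence threshold."""
    import math

    sub = presence[list(rows)]
    occ = sub.sum(axis=0)
    observed = (occ >= 1).sum()
    need = math.ceil(prevalence * len(rows) - 1e-9)
    return (occ >= max(need, 1)).sum() / observed


def exhaustive_core_length_null(presence, draw, prevalence=0.8):
    """Core length of every size-`draw` subset of the pooled rows."""
    n = presence.shape[0]
    return [
        brute_relative_core_length(presence, rows, prevalence)
        for rows in combinations(range(n), draw)
    ]
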