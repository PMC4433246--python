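"""Distance-based permutational MANOVA and the level-wise group tests.

The pseudo-F statistic partitions the sum of squared distances: with n
samples in a groups, SS_total = sum of squared pairwise distances / n,
SS_within the analogous within-group quantity, SS_between the
difference, and

    F = (SS_between / (a - 1)) / (SS_within / (n - a)).

Significance comes from permuting group labels (one-sided, large F);
small designs can be enumerated exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .beta import binary_jaccard, manhattan_distance
from .metadata import SampleMetadata
from .preprocess import aggregate_by_rank, arcsin_sqrt
from .table import OtuTable
from .taxonomy import TaxonomyMap


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int
    n: int
    n_groups: int
    exhaustive: bool = False


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, k: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for j in range(k):
        idx = np.flatnonzero(codes == j)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_decomposition(d2, codes, k)
    ss_between = ss_total - ss_within
    if n - k <= 0 or ss_within <= 0:
        return np.inf, (ss_between / ss_total if ss_total > 0 else 0.0)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    permutations: int = 999,
    seed_or_rng=0,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """Permutational MANOVA of a distance matrix against one factor.

    ``exhaustive=True`` enumerates every label ordering (feasible for
    n <= 8 or so); ``None`` auto-enables it when the orderings are no
    more numerous than ``permutations``.  Monte-Carlo p-values use the
    (b+1)/(B+1) convention; exhaustive p-values are exact fractions.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    labels = groups.loc[list(dm.ids)].astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    codes = labels.map({c: i for i, c in enumerate(names)}).to_numpy()
    d = np.asarray(dm.data, dtype=float)
    d2 = d ** 2
    n, k = len(codes), len(names)
    f_obs, r2 = _pseudo_f(d2, codes, k)
    if exhaustive is None:
        exhaustive = factorial(n) <= permutations
    if exhaustive:
        total = hits = 0
        for perm in _iter_permutations(range(n)):
            f_perm, _ = _pseudo_f(d2, codes[list(perm)], k)
            hits += f_perm >= f_obs - 1e-12
            total += 1
        p = hits / total
        b = total
    else:
        hits = 0
        for _ in range(permutations):
            f_perm, _ = _pseudo_f(d2, codes[rng.permutation(n)], k)
            hits += f_perm >= f_obs - 1e-12
        p = (hits + 1) / (permutations + 1)
        b = permutations
    return PermanovaResult(
        factor=groups.name or "",
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        permutations=b,
        n=n,
        n_groups=k,
        exhaustive=bool(exhaustive),
    )


LEVELS = ("otu", "species", "genus", "family", "order", "class", "phylum")


def levelwise_group_tests(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    factor: str,
    levels=LEVELS,
    permutations: int = 999,
    seed_or_rng=0,
) -> dict[str, PermanovaResult]:
    """PERMANOVA of one host factor at each bacterial taxonomic level.

    At each rank: aggregate -> relative abundance -> arcsin(sqrt) ->
    Manhattan distance -> PERMANOVA.  At the OTU level the same
    abundance pathway is used, plus a presence/absence + Jaccard
    variant reported under the key ``"otu_jaccard"``.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    groups = metadata.groups(factor, table.sample_ids)
    groups.name = factor
    out: dict[str, PermanovaResult] = {}
    for level in levels:
        if level == "otu":
            level_table = table
        else:
            level_table = aggregate_by_rank(table, taxonomy, level)
        transformed = arcsin_sqrt(level_table.relative())
        dm = manhattan_distance(transformed)
        out[level] = permanova(dm, groups, permutations, rng)
        if level == "otu":
            out["otu_jaccard"] = permanova(
                binary_jaccard(level_table), groups, permutations, rng
            )
    return out
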