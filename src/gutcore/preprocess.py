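"""OTU filtering rules, rarefaction, rank aggregation and transforms.

The retention rules mirror a conservative amplicon workflow: an OTU is
kept when it occurs in at least two samples, or in a single sample but
backed by at least four reads (">3 reads"); OTUs assigned to an
excluded phylum (by default Cyanobacteria, read as chloroplasts of
ingested material) are removed unless their lineage matches one of the
exception clades (the gut Melainabacteria: YS2 / 4C0d-2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import OtuTable, OtuTableError
from .taxonomy import RANKS, UNASSIGNED, TaxonomyMap, parse_lineage, rank_index


@dataclass
class FilterReport:
    """Which OTUs a filter removed, rule by rule."""

    rule: str
    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "otu_id": otu}
            for rule, otus in self.removed.items()
            for otu in otus
        ]
        return pd.DataFrame(rows, columns=["rule", "otu_id"])


def filter_low_occurrence(
    table: OtuTable, min_samples: int = 2, singleton_min_reads: int = 4
) -> tuple[OtuTable, FilterReport]:
    """Keep OTUs shared by >= ``min_samples`` samples, plus singletons
    (single-sample OTUs) with >= ``singleton_min_reads`` total reads."""
    occ = (table.data > 0).sum(axis=0)
    tot = table.data.sum(axis=0)
    keep = (occ >= min_samples) | ((occ == 1) & (tot >= singleton_min_reads))
    removed = [o for o, k in keep.items() if not k]
    report = FilterReport(
        rule="low_occurrence",
        n_input=len(table.otu_ids),
        removed={"low_occurrence": removed},
    )
    return table.select_otus([o for o, k in keep.items() if k]), report


def filter_taxa(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    exclude: str = "Cyanobacteria",
    exceptions: tuple[str, ...] = ("Melainabacteria", "YS2", "4C0d-2"),
) -> tuple[OtuTable, FilterReport]:
    """Remove OTUs whose lineage contains the ``exclude`` name at any
    rank, unless any exception name also occurs in the lineage."""
    if not exclude:
        raise ValueError("exclude pattern must be a non-empty taxon name")
    taxonomy = taxonomy.ensure_covers(table.otu_ids)
    removed = []
    for otu in table.otu_ids:
        names = {n for n in taxonomy[otu] if n is not None}
        if exclude in names and not names.intersection(exceptions):
            removed.append(otu)
    keep = [o for o in table.otu_ids if o not in set(removed)]
    report = FilterReport(
        rule="taxon_exclusion",
        n_input=len(table.otu_ids),
        removed={"taxon_exclusion": removed},
    )
    return table.select_otus(keep), report


def rarefy(
    table: OtuTable,
    depth: int,
    seed_or_rng,
    on_below_depth: str = "drop",
) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw per sample).

    Samples with fewer total reads are dropped with a warning, or raise
    when ``on_below_depth="error"``.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    totals = table.sample_sums()
    shallow = list(totals.index[totals < depth])
    if shallow and on_below_depth == "error":
        raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow}",
            stacklevel=2,
        )
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    if not keep:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rows = []
    for s in keep:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.vstack(rows), index=keep, columns=table.otu_ids)
    return OtuTable(out, table.marker)


def aggregate_by_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU columns into taxon columns at one rank.

    Column labels are prefixed lineage strings truncated at the rank
    (so the output can itself be re-aggregated at a shallower rank);
    OTUs unassigned at the rank keep their maximal assigned prefix,
    and fully unassigned OTUs pool into an explicit ``"unassigned"``
    column.
    """
    rank_index(rank)  # validates
    taxonomy = taxonomy.ensure_covers(table.otu_ids)
    labels = {otu: taxonomy.label_at(otu, rank) for otu in table.otu_ids}
    grouped = table.data.T.groupby(table.data.columns.map(labels)).sum().T
    # stable, deterministic column order: assigned labels sorted, unassigned last
    cols = sorted(c for c in grouped.columns if c != UNASSIGNED)
    if UNASSIGNED in grouped.columns:
        cols.append(UNASSIGNED)
    return OtuTable(grouped[cols], table.marker)


def reaggregate(table: OtuTable, rank: str) -> OtuTable:
    """Re-aggregate a rank table (lineage-string columns) at a shallower rank."""
    tax = TaxonomyMap()
    for col in table.otu_ids:
        if col == UNASSIGNED:
            tax.set(col, tuple([None] * len(RANKS)))
        else:
            tax.set(col, parse_lineage(col))
    return aggregate_by_rank(table, tax, rank)


def to_relative(table: OtuTable) -> pd.DataFrame:
    """Fractional abundances; rows sum to one."""
    return table.relative()


def arcsin_sqrt(fractions: pd.DataFrame, include_sqrt: bool = True) -> pd.DataFrame:
    """Variance-stabilizing arcsine transform x -> arcsin(sqrt(x)).

    The square root is the textbook convention for proportions and the
    default here; ``include_sqrt=False`` gives the bare arcsine.
    Output range is [0, pi/2] either way (bare arcsine needs x <= 1).
    """
    arr = fractions.to_numpy(dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("arcsin transform expects fractional data in [0, 1]")
    out = np.arcsin(np.sqrt(arr)) if include_sqrt else np.arcsin(arr)
    return pd.DataFrame(out, index=fractions.index, columns=fractions.columns)
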