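"""Greengenes-style 7-rank lineages and the OTU -> lineage map.

Lineage strings use the familiar rank prefixes
``k__; p__; c__; o__; f__; g__; s__``.  A lineage may be truncated at
any depth (classifier ran out of confidence); ranks after the
truncation point are unassigned.  Because the two 16S markers have
disjoint OTU id spaces, taxonomy names are the only join key between
markers -- so lineage handling is deliberately strict about rank order.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNASSIGNED = "unassigned"


class TaxonomyError(ValueError):
    pass


Lineage = tuple  # 7-tuple of str|None, aligned with RANKS


def parse_lineage(text: str) -> Lineage:
    """Parse ``"k__Bacteria; p__Firmicutes"`` into a 7-slot lineage.

    Tokens must carry the canonical prefixes in canonical order with no
    gaps before the truncation point; an empty token (``"g__"``) is an
    explicit unassigned rank and ends the assigned part.
    """
    names: list[str | None] = [None] * len(RANKS)
    tokens = [t.strip() for t in text.split(";") if t.strip() != ""]
    for pos, token in enumerate(tokens):
        if pos >= len(RANKS):
            raise TaxonomyError(f"more than {len(RANKS)} ranks in {text!r}")
        prefix = PREFIXES[pos]
        if not token.startswith(prefix):
            raise TaxonomyError(
                f"rank {pos + 1} of {text!r}: expected prefix {prefix!r}, got {token!r}"
            )
        name = token[len(prefix):].strip()
        names[pos] = name if name else None
    # no gaps: once unassigned, everything deeper must be unassigned
    seen_gap = False
    for name in names:
        if name is None:
            seen_gap = True
        elif seen_gap:
            raise TaxonomyError(f"assigned rank after unassigned rank in {text!r}")
    return tuple(names)


def lineage_to_string(lineage: Lineage, depth: int | None = None) -> str:
    """Serialize back to the prefixed form, truncated at the last assigned
    rank (or at ``depth`` ranks when given)."""
    n = len(RANKS) if depth is None else depth
    parts = []
    for prefix, name in zip(PREFIXES[:n], lineage[:n]):
        if name is None:
            break
        parts.append(prefix + name)
    return "; ".join(parts)


def rank_index(rank: str) -> int:
    if rank not in RANKS:
        raise TaxonomyError(f"unknown rank {rank!r}; one of {RANKS}")
    return RANKS.index(rank)


class TaxonomyMap(Mapping):
    """Mapping from OTU id to a 7-rank lineage."""

    def __init__(self, entries: Mapping[str, Lineage] | None = None):
        self._entries: dict[str, Lineage] = {}
        if entries:
            for otu, lin in entries.items():
                self.set(otu, lin)

    def set(self, otu_id: str, lineage: Lineage) -> None:
        lineage = tuple(lineage)
        if len(lineage) != len(RANKS):
            raise TaxonomyError(
                f"lineage for {otu_id!r} must have {len(RANKS)} slots"
            )
        self._entries[str(otu_id)] = lineage

    def set_string(self, otu_id: str, text: str) -> None:
        self.set(otu_id, parse_lineage(text))

    def __getitem__(self, otu_id: str) -> Lineage:
        return self._entries[otu_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def name_at(self, otu_id: str, rank: str) -> str | None:
        """Taxon name of an OTU at one rank, or None when unassigned."""
        return self._entries[otu_id][rank_index(rank)]

    def label_at(self, otu_id: str, rank: str) -> str:
        """Prefixed lineage string truncated at ``rank``; the label used
        for rank aggregation and cross-marker matching.

        An OTU unassigned at ``rank`` keeps its maximal assigned prefix
        (so aggregation loses no upper-rank information and coarse
        re-aggregation of a fine rank table matches direct
        aggregation); a fully unassigned OTU gets ``"unassigned"``."""
        idx = rank_index(rank)
        lineage = self._entries[otu_id]
        label = lineage_to_string(lineage, depth=idx + 1)
        return label if label else UNASSIGNED

    def ensure_covers(self, otu_ids: Iterable[str], warn=None) -> "TaxonomyMap":
        """Return a map covering every listed OTU; ids absent from the map
        get a fully-unassigned lineage (reported through ``warn``)."""
        out = TaxonomyMap(self._entries)
        empty: Lineage = tuple([None] * len(RANKS))
        for otu in otu_ids:
            if otu not in out._entries:
                if warn is not None:
                    warn(f"OTU {otu!r} missing from taxonomy; treated as unassigned")
                out._entries[str(otu)] = empty
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonomyMap):
            return NotImplemented
        return self._entries == other._entries
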