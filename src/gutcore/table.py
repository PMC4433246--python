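"""OTU count tables.

The central container of every analysis stage: an integer read-count
matrix with samples as rows and OTUs as columns, tagged with the 16S
marker (amplicon) it was derived from, e.g. ``"V12"`` or ``"V34"``.
Counts stay integers throughout; relative abundances are computed on
demand and never stored, because rarefaction needs raw reads.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class OtuTableError(ValueError):
    """Raised when a count matrix violates the OtuTable contract."""


def _first_duplicate(items: Sequence) -> object | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


class OtuTable:
    """Validated samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and OTU ids as columns.
        Values must be non-negative and integral (integer dtype, or a
        float dtype holding whole numbers, as BIOM JSON produces).
    marker
        Free-form amplicon label ("V12", "V34", ...).
    """

    def __init__(self, counts: pd.DataFrame, marker: str = ""):
        if not isinstance(counts, pd.DataFrame):
            raise OtuTableError("counts must be a pandas DataFrame")
        dup = _first_duplicate(list(counts.index))
        if dup is not None:
            raise OtuTableError(f"duplicate sample id: {dup!r}")
        dup = _first_duplicate(list(counts.columns))
        if dup is not None:
            raise OtuTableError(f"duplicate OTU id: {dup!r}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = self._locate(counts, lambda v: not np.isreal(v))
            raise OtuTableError(f"non-numeric count at {bad}")
        if values.size:
            arr = np.asarray(values, dtype=float)
            if np.isnan(arr).any():
                bad = self._locate(counts, lambda v: pd.isna(v))
                raise OtuTableError(f"missing count at {bad}")
            if (arr < 0).any():
                bad = self._locate(counts, lambda v: v < 0)
                raise OtuTableError(f"negative count at {bad}")
            if (arr != np.floor(arr)).any():
                bad = self._locate(counts, lambda v: v != int(v))
                raise OtuTableError(f"non-integer count at {bad}")
        self.data = counts.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.marker = str(marker)

    @staticmethod
    def _locate(df: pd.DataFrame, pred) -> str:
        for s in df.index:
            for o in df.columns:
                v = df.at[s, o]
                try:
                    if pred(v):
                        return f"sample {s!r}, OTU {o!r} (value {v!r})"
                except (TypeError, ValueError):
                    return f"sample {s!r}, OTU {o!r} (value {v!r})"
        return "unknown cell"

    # -- basic views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        """Raw count matrix as an int array (samples x OTUs)."""
        return self.data.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def otu_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view."""
        return self.data > 0

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1).

        Raises on empty samples: a zero-read sample has no composition.
        """
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise OtuTableError(f"sample {empty!r} has zero total reads")
        return self.data.div(totals, axis=0)

    # -- subsetting ----------------------------------------------------

    def select_samples(self, ids: Iterable[str]) -> "OtuTable":
        ids = list(ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise OtuTableError(f"unknown sample ids: {missing}")
        return OtuTable(self.data.loc[ids], self.marker)

    def select_otus(self, ids: Iterable[str]) -> "OtuTable":
        ids = list(ids)
        missing = [o for o in ids if o not in self.data.columns]
        if missing:
            raise OtuTableError(f"unknown OTU ids: {missing}")
        return OtuTable(self.data[ids], self.marker)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.data.columns[(self.data > 0).any(axis=0)]
        return OtuTable(self.data[keep], self.marker)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.marker == other.marker and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable(marker={self.marker!r}, {n} samples x {m} OTUs)"
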