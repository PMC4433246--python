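"""Per-specimen host metadata: the grouping factors of every test.

Each gut sample belongs to one host individual, and each host species
maps to exactly one genus, tribe, diet class and origin (wild or lab).
All downstream grouping -- species, genus, tribe, diet -- is resolved
through this table.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

REQUIRED_COLUMNS = ("host_species", "host_genus", "host_tribe", "diet", "origin")
DIETS = ("zooplanktivore", "scale-eater", "omnivore")
ORIGINS = ("wild", "lab")
FACTORS = ("host_species", "host_genus", "host_tribe", "diet", "origin")


class MetadataError(ValueError):
    pass


class SampleMetadata:
    """Sample table indexed by sample id with host grouping columns."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise MetadataError(f"metadata missing columns: {missing}")
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise MetadataError(f"duplicate sample id: {dup!r}")
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        for c in REQUIRED_COLUMNS:
            frame[c] = frame[c].astype(str)
        bad_diet = set(frame["diet"]) - set(DIETS)
        if bad_diet:
            raise MetadataError(f"unknown diet labels: {sorted(bad_diet)}")
        bad_origin = set(frame["origin"]) - set(ORIGINS)
        if bad_origin:
            raise MetadataError(f"unknown origin labels: {sorted(bad_origin)}")
        # one species -> one (genus, tribe, diet, origin)
        per_species = frame.groupby("host_species")[
            ["host_genus", "host_tribe", "diet", "origin"]
        ].nunique()
        inconsistent = per_species[(per_species > 1).any(axis=1)]
        if len(inconsistent):
            raise MetadataError(
                "species with inconsistent attributes: "
                f"{list(inconsistent.index)}"
            )
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups(self, factor: str, samples: Iterable[str] | None = None) -> pd.Series:
        """Group label per sample for one factor (host_species, diet, ...)."""
        if factor not in FACTORS:
            raise MetadataError(f"unknown grouping factor {factor!r}; one of {FACTORS}")
        series = self.frame[factor]
        if samples is not None:
            samples = list(samples)
            missing = [s for s in samples if s not in series.index]
            if missing:
                raise MetadataError(f"samples without metadata: {missing}")
            series = series.loc[samples]
        return series

    def wild_samples(self, samples: Iterable[str] | None = None) -> list[str]:
        sel = self.frame["origin"] == "wild"
        ids = list(self.frame.index[sel])
        if samples is not None:
            pool = set(samples)
            ids = [s for s in ids if s in pool]
        return ids

    def samples_of_species(self, species: str) -> list[str]:
        return list(self.frame.index[self.frame["host_species"] == species])

    def species(self, wild_only: bool = False) -> list[str]:
        frame = self.frame
        if wild_only:
            frame = frame[frame["origin"] == "wild"]
        return sorted(frame["host_species"].unique())

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        """Every table sample must have a metadata row."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise MetadataError(f"samples without metadata rows: {missing}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.frame.equals(other.frame)
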