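"""Core-microbiota computation and its permutation statistics.

The core is defined by up to three stacked criteria: (i) presence in at
least a prevalence fraction (default 80%) of the in-scope individuals,
the threshold taken as a ceiling so "at least 80%" is a hard lower
bound; (ii) presence in at least one individual of every in-scope host
species; (iii) for cores at a taxonomic rank (never for OTUs, whose id
spaces are marker-specific), recovery by both 16S markers.  The default
scope is wild individuals only; lab-reared fish are excluded from both
the core and every permutation pool.

The *relative core length* of a set of individuals is the fraction of
the OTUs any of them carries that are core (>= the prevalence threshold
of them).  Whether a species' conspecific core is longer than chance is
judged against repeatedly drawing the same number of individuals from
the pooled wild fish with species labels ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metadata import SampleMetadata
from .stats import RankTestResult, rank_sum_continuity
from .table import OtuTable
from .taxonomy import UNASSIGNED


def prevalence_count(n: int, prevalence: float, mode: str = "ceil") -> int:
    """Individuals required for core membership among n in-scope fish."""
    if mode == "ceil":
        return max(1, math.ceil(prevalence * n - 1e-9))
    if mode == "floor":
        return max(1, math.floor(prevalence * n + 1e-9))
    raise ValueError("mode must be 'ceil' or 'floor'")


@dataclass
class CoreSet:
    level: str                      # "otu" or a taxonomic rank
    members: list[str]
    prevalence: float
    n_individuals: int
    require_every_species: bool
    scope: str                      # "wild" or "all"
    marker: str = ""
    cross_marker: bool = False

    def __contains__(self, item) -> bool:
        return item in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def core_members(
    table: OtuTable,
    metadata: SampleMetadata,
    prevalence: float = 0.8,
    require_every_species: bool = True,
    scope: str = "wild",
    level: str = "otu",
    threshold_mode: str = "ceil",
) -> CoreSet:
    """Members (OTUs, or taxa of an already rank-aggregated table)
    satisfying the prevalence and per-species-representation criteria."""
    if scope not in ("wild", "all"):
        raise ValueError("scope must be 'wild' or 'all'")
    metadata.validate_against(table.sample_ids)
    samples = (
        metadata.wild_samples(table.sample_ids) if scope == "wild" else table.sample_ids
    )
    if not samples:
        raise ValueError("no in-scope samples for core computation")
    sub = table.select_samples(samples)
    pres = sub.presence()
    need = prevalence_count(len(samples), prevalence, threshold_mode)
    ok = pres.sum(axis=0) >= need
    if require_every_species:
        species = metadata.groups("host_species", samples)
        for sp in species.unique():
            sp_pres = pres.loc[species.index[species == sp]].any(axis=0)
            ok &= sp_pres
    members = [m for m in sub.otu_ids if ok[m] and m != UNASSIGNED]
    return CoreSet(
        level=level,
        members=members,
        prevalence=prevalence,
        n_individuals=len(samples),
        require_every_species=require_every_species,
        scope=scope,
        marker=table.marker,
    )


def cross_marker_core(core_a: CoreSet, core_b: CoreSet) -> CoreSet:
    """Taxa recovered as core by both markers (taxon-name intersection).

    Only defined at a taxonomic rank: OTU ids are marker-specific, so
    an OTU-level intersection would be meaningless.
    """
    if core_a.level == "otu" or core_b.level == "otu":
        raise ValueError("cross-marker cores are defined for taxa, not OTUs")
    if core_a.level != core_b.level:
        raise ValueError(
            f"cores at different ranks: {core_a.level!r} vs {core_b.level!r}"
        )
    shared = sorted(
        (set(core_a.members) & set(core_b.members)) - {UNASSIGNED, ""}
    )
    return CoreSet(
        level=core_a.level,
        members=shared,
        prevalence=core_a.prevalence,
        n_individuals=core_a.n_individuals,
        require_every_species=core_a.require_every_species
        and core_b.require_every_species,
        scope=core_a.scope,
        marker=f"{core_a.marker}+{core_b.marker}",
        cross_marker=True,
    )


def relative_core_length(
    table: OtuTable,
    individuals,
    prevalence: float = 0.8,
    threshold_mode: str = "ceil",
) -> float:
    """Core OTUs (present in >= ceil(prevalence * n) of the n
    individuals) over OTUs present in any of them."""
    individuals = list(individuals)
    if not individuals:
        raise ValueError("need at least one individual")
    pres = table.select_samples(individuals).presence().to_numpy()
    occ = pres.sum(axis=0)
    observed = int((occ >= 1).sum())
    if observed == 0:
        raise ValueError("individuals carry no OTUs at all")
    need = prevalence_count(len(individuals), prevalence, threshold_mode)
    return float((occ >= need).sum() / observed)


@dataclass
class CoreLengthTestResult:
    species: str
    n_conspecifics: int
    observed: float
    null_values: np.ndarray
    draw: int
    permutations: int

    @property
    def p_value(self) -> float:
        b = int((self.null_values >= self.observed - 1e-12).sum())
        return (b + 1) / (self.permutations + 1)


def _null_core_lengths(
    pres: np.ndarray, draw: int, permutations: int, prevalence: float,
    threshold_mode: str, rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised null: core length of `draw` individuals sampled
    without replacement from the pooled rows, `permutations` times."""
    n = pres.shape[0]
    need = prevalence_count(draw, prevalence, threshold_mode)
    out = np.empty(permutations)
    for b in range(permutations):
        rows = pres[rng.choice(n, size=draw, replace=False)]
        occ = rows.sum(axis=0)
        observed = (occ >= 1).sum()
        out[b] = (occ >= need).sum() / observed if observed else 0.0
    return out


def core_length_permutation_test(
    table: OtuTable,
    metadata: SampleMetadata,
    draw: int = 5,
    permutations: int = 1000,
    prevalence: float = 0.8,
    seed_or_rng=0,
    threshold_mode: str = "ceil",
    min_conspecifics: int = 2,
) -> dict[str, CoreLengthTestResult]:
    """One-sided test per wild species: is the conspecific relative core
    length larger than that of random same-size pools of individuals?

    The shared null shuffles species labels by drawing ``draw`` wild
    individuals at random (without replacement) ``permutations`` times.
    Species contributing fewer than ``min_conspecifics`` individuals are
    excluded (a single fish has no conspecific core).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    metadata.validate_against(table.sample_ids)
    wild = metadata.wild_samples(table.sample_ids)
    if len(wild) < draw:
        raise ValueError(
            f"need at least draw={draw} wild individuals, found {len(wild)}"
        )
    pres = table.select_samples(wild).presence().to_numpy()
    null = _null_core_lengths(
        pres, draw, permutations, prevalence, threshold_mode, rng
    )
    species = metadata.groups("host_species", wild)
    results: dict[str, CoreLengthTestResult] = {}
    for sp in sorted(species.unique()):
        members = list(species.index[species == sp])
        if len(members) < min_conspecifics:
            continue
        obs = relative_core_length(table, members, prevalence, threshold_mode)
        results[sp] = CoreLengthTestResult(
            species=sp,
            n_conspecifics=len(members),
            observed=obs,
            null_values=null,
            draw=draw,
            permutations=permutations,
        )
    return results


@dataclass
class SharedOtuResult:
    pairs: pd.DataFrame          # sample_a, sample_b, shared_fraction, kind
    test: RankTestResult

    @property
    def intra(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "intra", "shared_fraction"].to_numpy()

    @property
    def inter(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "inter", "shared_fraction"].to_numpy()


def shared_otu_proportions(
    table: OtuTable,
    metadata: SampleMetadata,
    scope_tribe: str | None = None,
    wild_only: bool = True,
) -> SharedOtuResult:
    """Pairwise shared-OTU fractions split into intra- vs inter-specific
    pairs, compared by a continuity-corrected rank-sum test.

    The shared fraction of a pair is Jaccard similarity,
    |A n B| / |A u B| of the two presence sets.  ``scope_tribe``
    restricts the comparison to one host tribe.
    """
    metadata.validate_against(table.sample_ids)
    samples = (
        metadata.wild_samples(table.sample_ids) if wild_only else table.sample_ids
    )
    if scope_tribe is not None:
        tribes = metadata.groups("host_tribe", samples)
        samples = [s for s in samples if tribes[s] == scope_tribe]
    if len(samples) < 3:
        raise ValueError("need at least 3 in-scope samples")
    pres = table.select_samples(samples).presence().to_numpy()
    species = metadata.groups("host_species", samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            union = np.logical_or(pres[i], pres[j]).sum()
            inter = np.logical_and(pres[i], pres[j]).sum()
            frac = inter / union if union else 0.0
            kind = "intra" if species.iloc[i] == species.iloc[j] else "inter"
            rows.append(
                {
                    "sample_a": samples[i],
                    "sample_b": samples[j],
                    "shared_fraction": frac,
                    "kind": kind,
                }
            )
    pairs = pd.DataFrame(rows)
    intra = pairs.loc[pairs["kind"] == "intra", "shared_fraction"]
    inter = pairs.loc[pairs["kind"] == "inter", "shared_fraction"]
    if len(intra) == 0 or len(inter) == 0:
        raise ValueError("both intra- and inter-specific pairs are required")
    test = rank_sum_continuity(intra, inter, alternative="greater")
    return SharedOtuResult(pairs=pairs, test=test)
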