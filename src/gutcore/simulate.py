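"""Synthetic paired-marker gut communities with a known ground truth.

The generator emulates the statistical structure of a desk-scale 454
cichlid-gut survey: six host species (five Perissodini plus a riverine
outgroup, one of them also as a lab-reared population), two 16S markers
("V12", "V34") with overlapping but non-identical OTU recovery, one
dominant OTU carrying ~30% of all reads, a family-wide core, per-species
core OTUs (~13-15% of each species' observed OTUs), taxa exclusive to
the outgroup (including a gut-Melainabacteria-like YS2 clade), a
quantitative diet enrichment of Clostridium-like taxa in scale-eaters,
sparse environmental noise, and variable library sizes.

Counts are multinomial draws from per-sample relative-abundance
vectors; the two markers share taxonomy labels but have disjoint OTU id
spaces, coupled by independent per-OTU dropout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .metadata import SampleMetadata
from .table import OtuTable
from .taxonomy import RANKS, TaxonomyMap, parse_lineage


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    genus: str
    tribe: str
    diet: str
    origin: str
    n_individuals: int


DEFAULT_SPECIES = (
    SpeciesSpec("Hapmic", "Haplotaxodon", "Perissodini", "zooplanktivore", "wild", 5),
    SpeciesSpec("Haptri", "Haplotaxodon", "Perissodini", "zooplanktivore", "wild", 4),
    SpeciesSpec("Plestr", "Plecodus", "Perissodini", "scale-eater", "wild", 5),
    SpeciesSpec("Permic", "Perissodus", "Perissodini", "scale-eater", "wild", 5),
    SpeciesSpec("Perecc", "Perissodus", "Perissodini", "scale-eater", "wild", 1),
    SpeciesSpec("Astbur", "Astatotilapia", "Tropheini", "omnivore", "wild", 5),
    SpeciesSpec("AstburLAB", "Astatotilapia", "Tropheini", "omnivore", "lab", 5),
)


@dataclass
class SimulationDesign:
    """Knobs of the synthetic community; defaults emulate the study
    conditions (sample layout, dominant-OTU share, conspecific core
    fraction, marker recovery)."""

    species: tuple = DEFAULT_SPECIES
    # family-wide core (shared by all host species), incl. the dominant OTU
    n_family_core: int = 20
    family_core_presence: float = 0.99
    dominant_mean: float = 0.30
    dominant_concentration: float = 30.0
    # per-species planted cores
    species_core_count: int = 17
    species_core_presence: float = 0.9
    species_core_leak: float = 0.03
    target_core_fraction: float = 0.14  # descriptive target, not a dial
    # shared accessory pool
    n_accessory: int = 350
    accessory_presence: float = 0.25
    # outgroup-exclusive taxa (planted in the single outgroup species)
    n_outgroup_exclusive: int = 30
    outgroup_presence: float = 0.6
    outgroup_species: str = "Astbur"
    # diet-associated quantitative enrichment
    n_diet_enriched: int = 8
    diet_enriched_presence: float = 0.6
    diet_fold: float = 3.0
    enriched_diet: str = "scale-eater"
    # environmental noise
    n_noise: int = 150
    noise_presence: float = 0.02
    # sequencing
    library_size_median: float = 8000.0
    library_size_sigma: float = 0.5
    marker_recovery: float = 0.9
    markers: tuple = ("V12", "V34")
    lab_retention: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "family_core_presence", "species_core_presence", "species_core_leak",
            "accessory_presence", "outgroup_presence", "diet_enriched_presence",
            "noise_presence", "marker_recovery", "lab_retention",
            "target_core_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_family_core", "species_core_count", "n_accessory",
            "n_outgroup_exclusive", "n_diet_enriched", "n_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_family_core < 1:
            raise ValueError("need at least the dominant family-core OTU")
        if self.diet_fold < 1:
            raise ValueError(f"diet_fold must be >= 1, got {self.diet_fold}")
        if not (0 < self.dominant_mean < 1):
            raise ValueError("dominant_mean must be in (0, 1)")
        if len(self.markers) < 1:
            raise ValueError("need at least one marker")
        self.species = tuple(self.species)
        self.markers = tuple(self.markers)

    def n_total_otus(self) -> int:
        n_sp_core = self.species_core_count * sum(
            1 for s in self.species if s.origin == "wild" and s.n_individuals >= 2
        )
        return (
            self.n_family_core + n_sp_core + self.n_accessory
            + self.n_outgroup_exclusive + self.n_diet_enriched + self.n_noise
        )

    def exchangeable(self) -> "SimulationDesign":
        """Variant with all species-specific planted structure and the
        diet enrichment switched off: wild individuals are statistically
        exchangeable (the null condition for calibration checks)."""
        return dataclasses.replace(
            self,
            species_core_count=0,
            n_outgroup_exclusive=0,
            diet_fold=1.0,
        )


@dataclass
class SyntheticTruth:
    """What was planted, for parameter-recovery tests."""

    dominant: str
    family_core: list[str]
    species_core: dict[str, list[str]]
    diet_enriched: list[str]
    diet_fold: float
    outgroup_exclusive: list[str]
    noise: list[str]
    species_of_sample: dict[str, str]
    marker_ids: dict[str, dict[str, str]]  # marker -> base id -> marker id

    def in_marker(self, marker: str, base_ids) -> list[str]:
        """Marker-specific ids of the planted base ids that the marker
        recovered (an id dropped by a marker cannot be found in it)."""
        mapping = self.marker_ids[marker]
        return [mapping[b] for b in base_ids if b in mapping]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------
# taxonomy templates
# ---------------------------------------------------------------------

_DOMINANT_LINEAGE = (
    "k__Bacteria; p__Fusobacteria; c__Fusobacteriia; o__Fusobacteriales; "
    "f__Fusobacteriaceae; g__Cetobacterium; s__somerae"
)

_CORE_TEMPLATES = (
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Clostridiaceae; g__Clostridium",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Enterobacteriales; f__Enterobacteriaceae; g__Plesiomonas",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Turicibacterales; f__Turicibacteraceae; g__Turicibacter",
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae",
    "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Neisseriales; f__Neisseriaceae",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Aeromonadales; f__Aeromonadaceae; g__Aeromonas",
    "k__Bacteria; p__Planctomycetes; c__Planctomycetia; o__Pirellulales; f__Pirellulaceae",
    "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales",
    "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__Verrucomicrobiales",
)

_ACCESSORY_PHYLA = (
    ("Firmicutes", "Clostridia", "Clostridiales"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales"),
    ("Proteobacteria", "Gammaproteobacteria", "Chromatiales"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales"),
    ("Planctomycetes", "Planctomycetia", "Gemmatales"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales"),
)

_OUTGROUP_TEMPLATES = (
    # gut Melainabacteria: Cyanobacteria by Greengenes placement, order YS2 --
    # these survive the Cyanobacteria filter through the exception list
    "k__Bacteria; p__Cyanobacteria; c__4C0d-2; o__YS2",
    "k__Bacteria; p__Chloroflexi; c__Caldilineae; o__Caldilineales; f__Caldilineaceae; g__Caldilinea",
    "k__Bacteria; p__TM7; c__TM7-3",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Lactococcus",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Methylocystaceae; g__Methylosinus",
)

_CHLOROPLAST_LINEAGE = (
    "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Streptophyta"
)

_DIET_LINEAGE = (
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; "
    "f__Clostridiaceae; g__Clostridium"
)


def _with_species_name(template: str, tag: str):
    """Fill the first unassigned rank of a template lineage with a
    per-OTU tag, so OTUs are distinct below a shared parent taxon."""
    lin = list(parse_lineage(template))
    for depth in range(len(RANKS)):
        if lin[depth] is None:
            lin[depth] = tag
            return tuple(lin)
    lin[-1] = f"{lin[-1]}_{tag}"
    return tuple(lin)


# ---------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------

def generate_tree(n_otus: int, seed_or_rng=0, tip_names=None) -> TreeNode:
    """Random rooted coalescent tree with positive branch lengths.

    Tips are named ``otu_0 ... otu_{n-1}`` unless ``tip_names`` is
    given.  The standard Kingman construction: lineages merge pairwise
    at exponentially distributed waiting times.
    """
    if n_otus < 2:
        raise ValueError(f"need at least 2 tips, got {n_otus}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    names = list(tip_names) if tip_names is not None else [f"otu_{i}" for i in range(n_otus)]
    if len(names) != n_otus:
        raise ValueError("tip_names length must equal n_otus")
    lineages = [(TreeNode(name=n), 0.0) for n in names]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += float(rng.exponential(1.0 / (k * (k - 1) / 2.0)))
        i, j = rng.choice(k, size=2, replace=False)
        (a, ha), (b, hb) = lineages[i], lineages[j]
        a.length = height - ha
        b.length = height - hb
        parent = TreeNode(children=[a, b])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, height))
    root = lineages[0][0]
    root.length = None
    return root


# ---------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------

def _sample_ids(design: SimulationDesign) -> tuple[list[str], dict[str, SpeciesSpec]]:
    ids, spec_of = [], {}
    for sp in design.species:
        for k in range(sp.n_individuals):
            sid = f"{sp.name}_{k + 1}"
            ids.append(sid)
            spec_of[sid] = sp
    return ids, spec_of


def _build_registry(design: SimulationDesign, rng: np.random.Generator):
    """Base OTU ids with compartment, lineage and base log-weight."""
    otus = []  # (id, compartment, owner, lineage, weight)

    def add(compartment, owner, lineage, mu, sigma=0.7):
        idx = len(otus)
        weight = float(np.exp(rng.normal(mu, sigma)))
        otus.append((f"otu_{idx:04d}", compartment, owner, lineage, weight))

    add("dominant", None, parse_lineage(_DOMINANT_LINEAGE), 0.0)
    for i in range(design.n_family_core - 1):
        template = _CORE_TEMPLATES[i % len(_CORE_TEMPLATES)]
        add("family_core", None, _with_species_name(template, f"fc{i}"), 3.0)
    wild_core_species = [
        s.name
        for s in design.species
        if s.origin == "wild" and s.n_individuals >= 2
    ]
    for sp_name in wild_core_species:
        for i in range(design.species_core_count):
            phylum, cls, order = _ACCESSORY_PHYLA[i % len(_ACCESSORY_PHYLA)]
            lineage = parse_lineage(
                f"k__Bacteria; p__{phylum}; c__{cls}; o__{order}; "
                f"f__{order}_f{i % 4}; g__{order}_{sp_name}_g{i}"
            )
            add("species_core", sp_name, lineage, 2.0)
    for i in range(design.n_diet_enriched):
        add("diet_enriched", None, _with_species_name(_DIET_LINEAGE, f"de{i}"), 2.5)
    for i in range(design.n_accessory):
        phylum, cls, order = _ACCESSORY_PHYLA[i % len(_ACCESSORY_PHYLA)]
        depth = i % 3
        text = f"k__Bacteria; p__{phylum}; c__{cls}; o__{order}"
        if depth >= 1:
            text += f"; f__{order}_f{i % 7}"
        if depth >= 2:
            text += f"; g__{order}_g{i % 11}"
        add("accessory", None, parse_lineage(text), 0.7)
    for i in range(design.n_outgroup_exclusive):
        template = _OUTGROUP_TEMPLATES[i % len(_OUTGROUP_TEMPLATES)]
        add("outgroup", design.outgroup_species, _with_species_name(template, f"og{i}"), 1.5)
    for i in range(design.n_noise):
        if i % 5 == 0:
            lineage = _with_species_name(_CHLOROPLAST_LINEAGE, f"nz{i}")
        else:
            phylum, cls, order = _ACCESSORY_PHYLA[i % len(_ACCESSORY_PHYLA)]
            lineage = parse_lineage(f"k__Bacteria; p__{phylum}; c__{cls}")
        add("noise", None, lineage, -3.5)
    return otus


def _presence_probability(
    design: SimulationDesign, compartment: str, owner, spec: SpeciesSpec
) -> float:
    if compartment == "dominant":
        return 1.0
    if compartment == "family_core":
        return design.family_core_presence
    if compartment == "species_core":
        base_species = spec.name.removesuffix("LAB")
        if owner in (spec.name, base_species):
            return design.species_core_presence
        return design.species_core_leak
    if compartment == "diet_enriched":
        return design.diet_enriched_presence
    if compartment == "accessory":
        return design.accessory_presence
    if compartment == "outgroup":
        base_species = spec.name.removesuffix("LAB")
        return design.outgroup_presence if base_species == owner and spec.origin == "wild" else 0.0
    if compartment == "noise":
        return design.noise_presence
    raise AssertionError(compartment)


def generate_dataset(design: SimulationDesign, seed: int | None = None):
    """Draw one synthetic dataset.

    Returns ``(tables, taxonomy, tree, metadata, truth)`` where
    ``tables`` maps marker name -> OtuTable.  Per sample: a relative-
    abundance vector is assembled (dominant share Beta-distributed,
    other present OTUs by jittered base weights, enrichment fold applied
    and renormalized), then read counts are independent multinomial
    draws per marker at that marker's library size over the OTUs the
    marker recovered.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sample_ids, spec_of = _sample_ids(design)
    otus = _build_registry(design, rng)
    n_otus = len(otus)
    base_ids = [o[0] for o in otus]

    # lab populations retain only a fraction of their source species'
    # non-family-core pool (diversity depletion in captivity)
    lab_names = {s.name for s in design.species if s.origin == "lab"}
    lab_available = {
        lab: rng.random(n_otus) < design.lab_retention for lab in lab_names
    }

    # per-marker recovery: an OTU dropped by every marker is reassigned
    # to one marker at random so every planted id stays resolvable
    recovery: dict[str, np.ndarray] = {
        m: rng.random(n_otus) < design.marker_recovery for m in design.markers
    }
    for idx in range(n_otus):
        if otus[idx][1] == "dominant":
            for m in design.markers:
                recovery[m][idx] = True
        elif not any(recovery[m][idx] for m in design.markers):
            lucky = design.markers[int(rng.integers(len(design.markers)))]
            recovery[lucky][idx] = True

    weights = np.array([o[4] for o in otus])
    compartments = [o[1] for o in otus]
    owners = [o[2] for o in otus]
    enriched_mask = np.array([c == "diet_enriched" for c in compartments])
    dominant_idx = 0

    a = design.dominant_mean * design.dominant_concentration
    b = (1 - design.dominant_mean) * design.dominant_concentration

    marker_counts = {
        m: np.zeros((len(sample_ids), n_otus), dtype=np.int64) for m in design.markers
    }
    for s_idx, sid in enumerate(sample_ids):
        spec = spec_of[sid]
        probs = np.array(
            [
                _presence_probability(design, compartments[k], owners[k], spec)
                for k in range(n_otus)
            ]
        )
        if spec.name in lab_names:
            non_core = np.array(
                [c not in ("dominant", "family_core") for c in compartments]
            )
            probs = np.where(non_core & ~lab_available[spec.name], 0.0, probs)
        present = rng.random(n_otus) < probs
        present[dominant_idx] = True
        sample_w = np.where(
            present, weights * np.exp(rng.normal(0.0, 0.6, size=n_otus)), 0.0
        )
        if spec.diet == design.enriched_diet and design.diet_fold != 1.0:
            sample_w = np.where(enriched_mask, sample_w * design.diet_fold, sample_w)
        dom_share = float(rng.beta(a, b))
        sample_w[dominant_idx] = 0.0
        for m in design.markers:
            # the dominant share applies to each library's reads, so it is
            # imposed after this marker's dropout of the minor taxa
            keep = recovery[m]
            rest = np.where(keep, sample_w, 0.0)
            total = rest.sum()
            p = np.zeros(n_otus)
            if total > 0:
                p = rest / total * (1.0 - dom_share)
                p[dominant_idx] = dom_share
            else:
                p[dominant_idx] = 1.0
            size = int(
                round(
                    float(
                        rng.lognormal(
                            np.log(design.library_size_median),
                            design.library_size_sigma,
                        )
                    )
                )
            )
            size = max(size, 1)
            marker_counts[m][s_idx] = rng.multinomial(size, p)

    taxonomy = TaxonomyMap()
    tables: dict[str, OtuTable] = {}
    marker_id_maps: dict[str, dict[str, str]] = {}
    for m in design.markers:
        cols = [k for k in range(n_otus) if recovery[m][k]]
        ids = [f"{m}_{base_ids[k]}" for k in cols]
        marker_id_maps[m] = {base_ids[k]: f"{m}_{base_ids[k]}" for k in cols}
        frame = pd.DataFrame(
            marker_counts[m][:, cols], index=sample_ids, columns=ids
        )
        tables[m] = OtuTable(frame, marker=m)
        for k, mid in zip(cols, ids):
            taxonomy.set(mid, otus[k][3])

    # one tree covering every marker-specific id: a random coalescent
    # over the base OTUs, with each base tip replaced by a short cherry
    # (or single pendant) of its marker ids
    base_tree = generate_tree(n_otus, rng, tip_names=base_ids)
    for tip in list(base_tree.tips()):
        base = tip.name
        mids = [
            marker_id_maps[m][base] for m in design.markers if base in marker_id_maps[m]
        ]
        if len(mids) == 1:
            tip.name = mids[0]
        else:
            tip.name = None
            tip.extend([TreeNode(name=mid, length=0.01) for mid in mids])
    tree = base_tree

    meta_rows = {
        sid: {
            "host_species": spec_of[sid].name,
            "host_genus": spec_of[sid].genus,
            "host_tribe": spec_of[sid].tribe,
            "diet": spec_of[sid].diet,
            "origin": spec_of[sid].origin,
        }
        for sid in sample_ids
    }
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    species_core: dict[str, list[str]] = {}
    for k in range(n_otus):
        if compartments[k] == "species_core":
            species_core.setdefault(owners[k], []).append(base_ids[k])
    truth = SyntheticTruth(
        dominant=base_ids[dominant_idx],
        family_core=[base_ids[k] for k in range(n_otus) if compartments[k] in ("dominant", "family_core")],
        species_core=species_core,
        diet_enriched=[base_ids[k] for k in range(n_otus) if compartments[k] == "diet_enriched"],
        diet_fold=design.diet_fold,
        outgroup_exclusive=[base_ids[k] for k in range(n_otus) if compartments[k] == "outgroup"],
        noise=[base_ids[k] for k in range(n_otus) if compartments[k] == "noise"],
        species_of_sample={sid: spec_of[sid].name for sid in sample_ids},
        marker_ids=marker_id_maps,
    )
    return tables, taxonomy, tree, metadata, truth
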