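"""End-to-end orchestration: preprocess -> diversity -> core ->
indicator stages over paired-marker inputs, with deterministic,
seed-reproducible tabular outputs.

Every stochastic stage draws its generator from the master seed keyed
by a stage name, so two runs with the same inputs, config and seed
produce byte-identical result files.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .alpha import METRICS, alpha_with_rarefaction, alpha_frame, species_mean_alpha
from .beta import (
    binary_jaccard,
    distance_boxplot_tests,
    distance_group_stats,
    jackknife_beta,
    manhattan_distance,
    unweighted_unifrac,
    weighted_unifrac,
)
from .config import AnalysisConfig
from .core import (
    core_length_permutation_test,
    core_members,
    cross_marker_core,
    relative_core_length,
    shared_otu_proportions,
)
from .indicator import concordant_indicators, indval, indval_significance
from .metadata import SampleMetadata
from .ordination import pcoa, procrustes_test
from .permanova import permanova
from .preprocess import (
    aggregate_by_rank,
    arcsin_sqrt,
    filter_low_occurrence,
    filter_taxa,
    rarefy,
)
from .simulate import SimulationDesign, generate_dataset
from .stats import mann_whitney_u, marker_concordance_r2
from .table import OtuTable
from .taxonomy import TaxonomyMap

log = logging.getLogger("gutcore")

CORE_RANKS = ("phylum", "class", "order", "family", "genus")
INDVAL_FACTORS = ("host_species", "host_genus", "host_tribe", "diet")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n", index=index)


def _dm_frame(dm) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def write_dataset(out_dir, tables, taxonomy, tree, metadata, truth=None) -> None:
    """Persist a dataset in the standard on-disk layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for marker, table in tables.items():
        gio.write_otu_table(table, out / f"table_{marker}.tsv")
    gio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
    gio.write_tree(tree, out / "tree.nwk")
    gio.write_metadata(metadata, out / "metadata.tsv")
    if truth is not None:
        truth.to_json(out / "truth.json")


def load_dataset(in_dir, markers=("V12", "V34")):
    """Read a dataset laid out as by :func:`write_dataset`."""
    src = Path(in_dir)
    metadata = gio.read_metadata(src / "metadata.tsv")
    tables = {
        m: gio.read_otu_table(src / f"table_{m}.tsv", marker=m, metadata=metadata)
        for m in markers
    }
    taxonomy = gio.read_taxonomy(src / "taxonomy.tsv")
    tree = gio.read_tree(src / "tree.nwk")
    return tables, taxonomy, tree, metadata


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    tables: dict[str, OtuTable] | None = None,
    taxonomy: TaxonomyMap | None = None,
    tree=None,
    metadata: SampleMetadata | None = None,
    design: SimulationDesign | None = None,
) -> dict[str, Path]:
    """Run every stage and write results under ``out_dir``.

    When no tables are given, a synthetic dataset is generated from
    ``design`` (default design, seeded from the master seed) and also
    written out.  Returns a name -> path map of the artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def emit(name: str, path: Path):
        artifacts[name] = path

    stage = "inputs"
    try:
        if tables is None:
            if design is None:
                design = SimulationDesign(seed=int(config.rng("simulate").integers(2**31)))
            log.info("simulating dataset (design seed %d)", design.seed)
            tables, taxonomy, tree, metadata, truth = generate_dataset(design)
            write_dataset(out / "inputs", tables, taxonomy, tree, metadata, truth)
            emit("inputs", out / "inputs")
        if taxonomy is None or metadata is None or tree is None:
            raise ValueError(
                "tables given without taxonomy, tree or metadata; "
                "provide all four or none"
            )
        for t in tables.values():
            metadata.validate_against(t.sample_ids)
        markers = sorted(tables)

        stage = "preprocess"
        filtered: dict[str, OtuTable] = {}
        report_rows = []
        for m in markers:
            t1, rep1 = filter_low_occurrence(
                tables[m], config.min_samples, config.singleton_min_reads
            )
            t2, rep2 = filter_taxa(
                t1, taxonomy, config.exclude_phylum, config.exceptions
            )
            filtered[m] = t2
            for rep in (rep1, rep2):
                report_rows.append(
                    {
                        "marker": m,
                        "rule": rep.rule,
                        "n_input": rep.n_input,
                        "n_removed": rep.n_removed,
                        "n_retained": rep.n_retained,
                    }
                )
            log.info(
                "%s: %d -> %d OTUs after filtering", m, rep1.n_input, rep2.n_retained
            )
        _write(pd.DataFrame(report_rows), out / "filter_report.tsv", index=False)
        emit("filter_report", out / "filter_report.tsv")

        stage = "alpha"
        species_means: dict[str, dict[str, pd.Series]] = {m: {} for m in markers}
        for m in markers:
            rng = config.rng(f"alpha:{m}")
            records = []
            for metric in METRICS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    recs = alpha_with_rarefaction(
                        filtered[m],
                        metric,
                        depth=config.depth,
                        iterations=config.iterations,
                        seed_or_rng=rng,
                        tree=tree,
                    )
                records.extend(recs)
                species_means[m][metric] = species_mean_alpha(recs, metadata)
            _write(alpha_frame(records), out / f"alpha_{m}.tsv")
            emit(f"alpha_{m}", out / f"alpha_{m}.tsv")
            # between-species comparisons on per-specimen rarefied means
            frame = alpha_frame(records)
            sp = metadata.groups("host_species", frame.index)
            rows = []
            species_list = sorted(sp.unique())
            for metric in METRICS:
                for i in range(len(species_list)):
                    for j in range(i + 1, len(species_list)):
                        a = frame.loc[sp == species_list[i], metric].dropna()
                        b = frame.loc[sp == species_list[j], metric].dropna()
                        if len(a) < 2 or len(b) < 2:
                            continue
                        res = mann_whitney_u(a, b)
                        rows.append(
                            {
                                "metric": metric,
                                "species_a": species_list[i],
                                "species_b": species_list[j],
                                "U": res.statistic,
                                "p": res.p_value,
                            }
                        )
            _write(pd.DataFrame(rows), out / f"alpha_tests_{m}.tsv", index=False)
            emit(f"alpha_tests_{m}", out / f"alpha_tests_{m}.tsv")
        if len(markers) == 2:
            ma, mb = markers
            rows = []
            for metric in METRICS:
                a, b = species_means[ma][metric], species_means[mb][metric]
                shared = sorted(set(a.index) & set(b.index))
                rows.append(
                    {
                        "metric": metric,
                        "r_squared": marker_concordance_r2(a[shared], b[shared]),
                        "n_species": len(shared),
                    }
                )
            _write(pd.DataFrame(rows), out / "alpha_marker_concordance.tsv", index=False)
            emit("alpha_marker_concordance", out / "alpha_marker_concordance.tsv")

        stage = "beta"
        coords: dict[tuple[str, str], pd.DataFrame] = {}
        for m in markers:
            rng = config.rng(f"beta:{m}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                even = rarefy(filtered[m], config.depth, rng, config.below_depth)
            dms = {
                "jaccard": binary_jaccard(even),
                "unweighted_unifrac": unweighted_unifrac(even, tree),
                "weighted_unifrac": weighted_unifrac(even, tree),
                "manhattan_arcsin": manhattan_distance(arcsin_sqrt(even.relative())),
            }
            for name, dm in dms.items():
                _write(_dm_frame(dm), out / f"dist_{name}_{m}.tsv")
                emit(f"dist_{name}_{m}", out / f"dist_{name}_{m}.tsv")
                ord_res = pcoa(dm)
                coords[(m, name)] = ord_res.samples
                _write(ord_res.samples, out / f"pcoa_{name}_{m}.tsv")
                emit(f"pcoa_{name}_{m}", out / f"pcoa_{name}_{m}.tsv")
            groups = metadata.groups("host_species", even.sample_ids)
            _write(
                distance_group_stats(dms["unweighted_unifrac"], groups),
                out / f"dist_stats_{m}.tsv",
            )
            emit(f"dist_stats_{m}", out / f"dist_stats_{m}.tsv")
            _write(
                distance_boxplot_tests(dms["unweighted_unifrac"], groups),
                out / f"dist_boxplot_tests_{m}.tsv",
                index=False,
            )
            emit(f"dist_boxplot_tests_{m}", out / f"dist_boxplot_tests_{m}.tsv")
            rows = []
            for factor in ("host_species", "host_tribe", "diet"):
                res = permanova(
                    dms["jaccard"],
                    metadata.groups(factor, even.sample_ids),
                    permutations=config.permutations,
                    seed_or_rng=config.rng(f"permanova:{m}:{factor}"),
                )
                rows.append(
                    {
                        "factor": factor,
                        "pseudo_F": res.pseudo_f,
                        "R2": res.r_squared,
                        "p": res.p_value,
                        "permutations": res.permutations,
                    }
                )
            _write(pd.DataFrame(rows), out / f"permanova_{m}.tsv", index=False)
            emit(f"permanova_{m}", out / f"permanova_{m}.tsv")
            jk = jackknife_beta(
                filtered[m],
                depth=config.depth,
                replicates=100,
                metric="jaccard",
                seed_or_rng=config.rng(f"jackknife:{m}"),
            )
            (out / f"upgma_{m}.nwk").write_text(jk.tree_newick + "\n")
            _write(jk.support_frame(), out / f"jackknife_support_{m}.tsv", index=False)
            emit(f"upgma_{m}", out / f"upgma_{m}.nwk")
            emit(f"jackknife_support_{m}", out / f"jackknife_support_{m}.tsv")
        if len(markers) == 2:
            ma, mb = markers
            rows = []
            for name in ("unweighted_unifrac", "weighted_unifrac"):
                ca, cb = coords[(ma, name)], coords[(mb, name)]
                shared = sorted(set(ca.index) & set(cb.index))
                res = procrustes_test(
                    ca.loc[shared],
                    cb.loc[shared],
                    permutations=config.permutations,
                    seed_or_rng=config.rng(f"procrustes:{name}"),
                )
                rows.append(
                    {"distance": name, "M2": res.m2, "p": res.p_value, "B": res.permutations}
                )
            _write(pd.DataFrame(rows), out / "procrustes.tsv", index=False)
            emit("procrustes", out / "procrustes.tsv")

        stage = "core"
        taxa_cores = {}
        for m in markers:
            core_otu = core_members(
                filtered[m], metadata, prevalence=config.prevalence, level="otu"
            )
            rows = [{"level": "otu", "member": mem} for mem in core_otu.members]
            taxa_cores[m] = {}
            for rank in CORE_RANKS:
                agg = aggregate_by_rank(filtered[m], taxonomy, rank)
                cs = core_members(
                    agg, metadata, prevalence=config.prevalence, level=rank
                )
                taxa_cores[m][rank] = cs
                rows.extend({"level": rank, "member": mem} for mem in cs.members)
            _write(pd.DataFrame(rows), out / f"core_{m}.tsv", index=False)
            emit(f"core_{m}", out / f"core_{m}.tsv")
            tests = core_length_permutation_test(
                filtered[m],
                metadata,
                draw=config.draw,
                permutations=config.permutations,
                prevalence=config.prevalence,
                seed_or_rng=config.rng(f"core_test:{m}"),
            )
            rows = [
                {
                    "species": r.species,
                    "n": r.n_conspecifics,
                    "relative_core_length": r.observed,
                    "null_mean": float(r.null_values.mean()),
                    "p": r.p_value,
                }
                for r in tests.values()
            ]
            _write(pd.DataFrame(rows), out / f"core_length_test_{m}.tsv", index=False)
            emit(f"core_length_test_{m}", out / f"core_length_test_{m}.tsv")
            shared = shared_otu_proportions(filtered[m], metadata)
            _write(shared.pairs, out / f"shared_otus_{m}.tsv", index=False)
            emit(f"shared_otus_{m}", out / f"shared_otus_{m}.tsv")
            _write(
                pd.DataFrame(
                    [
                        {
                            "W": shared.test.statistic,
                            "p": shared.test.p_value,
                            "median_intra": float(np.median(shared.intra)),
                            "median_inter": float(np.median(shared.inter)),
                        }
                    ]
                ),
                out / f"shared_otus_test_{m}.tsv",
                index=False,
            )
            emit(f"shared_otus_test_{m}", out / f"shared_otus_test_{m}.tsv")
        if len(markers) == 2:
            ma, mb = markers
            rows = []
            for rank in CORE_RANKS:
                both = cross_marker_core(taxa_cores[ma][rank], taxa_cores[mb][rank])
                rows.extend({"level": rank, "member": mem} for mem in both.members)
            _write(pd.DataFrame(rows, columns=["level", "member"]),
                   out / "core_both_markers.tsv", index=False)
            emit("core_both_markers", out / "core_both_markers.tsv")

        stage = "indval"
        for factor in INDVAL_FACTORS:
            per_marker = {}
            for m in markers:
                agg = aggregate_by_rank(filtered[m], taxonomy, "genus")
                clusters = metadata.groups(factor, agg.sample_ids)
                res = indval(agg, clusters)
                p = indval_significance(
                    agg,
                    clusters,
                    permutations=config.permutations,
                    seed_or_rng=config.rng(f"indval:{m}:{factor}"),
                )
                per_marker[m] = (res, p)
                summary = res.summary.copy()
                summary["p"] = p
                _write(summary, out / f"indval_{factor}_{m}.tsv")
                emit(f"indval_{factor}_{m}", out / f"indval_{factor}_{m}.tsv")
            if len(markers) == 2:
                (ra, pa), (rb, pb) = per_marker[markers[0]], per_marker[markers[1]]
                conc = concordant_indicators(
                    ra, pa, rb, pb, alpha=config.alpha, min_indval=config.min_indval
                )
                _write(conc, out / f"indicators_{factor}.tsv", index=False)
                emit(f"indicators_{factor}", out / f"indicators_{factor}.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    config.to_json(out / "config.json")
    emit("config", out / "config.json")
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
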