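"""Alpha diversity: Chao1, Shannon entropy, Faith's phylogenetic
diversity, rarefaction-averaged estimates and rarefaction curves.

Shannon defaults to log base 2 (bits), the convention of the classic
amplicon toolchain; Chao1 defaults to the bias-corrected estimator so
that zero doubletons stay well-defined; Faith's PD follows the "whole
tree" convention and includes the path to the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .preprocess import rarefy
from .table import OtuTable

METRICS = ("chao1", "shannon", "faith_pd")


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from an abundance vector.

    Bias-corrected: S_obs + F1 (F1 - 1) / (2 (F2 + 1)); classic:
    S_obs + F1^2 / (2 F2), where F1/F2 are singleton/doubleton counts.
    """
    arr = np.asarray(counts)
    if arr.sum() == 0:
        raise ValueError("chao1 is undefined for an all-zero vector")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic falls back when F2=0
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy -sum p log_base p over non-zero proportions."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("shannon is undefined for an empty vector")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(present_otus, tree: skbio.TreeNode) -> float:
    """Total branch length of the minimal subtree spanning the present
    tips and the root (whole-tree convention)."""
    present = set(present_otus)
    if not present:
        raise ValueError("faith_pd is undefined for an empty OTU set")
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(present - tip_names)
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing}")
    total = 0.0
    observed: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            obs = node.name in present
        else:
            obs = any(observed[id(c)] for c in node.children)
        observed[id(node)] = obs
        if obs and node.parent is not None and node.length:
            total += node.length
    return total


@dataclass
class AlphaRecord:
    sample_id: str
    metric: str
    values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _metric_value(metric: str, counts: np.ndarray, otu_ids, tree) -> float:
    if metric == "chao1":
        return chao1(counts)
    if metric == "shannon":
        return shannon(counts)
    if metric == "faith_pd":
        present = [o for o, c in zip(otu_ids, counts) if c > 0]
        return faith_pd(present, tree)
    raise ValueError(f"unknown alpha metric {metric!r}; one of {METRICS}")


def alpha_with_rarefaction(
    table: OtuTable,
    metric: str,
    depth: int = 500,
    iterations: int = 10,
    seed_or_rng=0,
    tree: skbio.TreeNode | None = None,
) -> list[AlphaRecord]:
    """Metric averaged over independent rarefactions to a common depth.

    Samples with fewer reads than ``depth`` are excluded with a warning.
    """
    if metric == "faith_pd" and tree is None:
        raise ValueError("faith_pd needs a phylogenetic tree")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    per_sample: dict[str, list[float]] = {}
    totals = table.sample_sums()
    eligible = [s for s in table.sample_ids if totals[s] >= depth]
    skipped = [s for s in table.sample_ids if totals[s] < depth]
    if skipped:
        warnings.warn(
            f"excluding {len(skipped)} sample(s) below depth {depth}: {skipped}",
            stacklevel=2,
        )
    if not eligible:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    sub = table.select_samples(eligible)
    for _ in range(iterations):
        rare = rarefy(sub, depth, rng)
        for s in rare.sample_ids:
            counts = rare.data.loc[s].to_numpy()
            per_sample.setdefault(s, []).append(
                _metric_value(metric, counts, rare.otu_ids, tree)
            )
    return [AlphaRecord(s, metric, vals) for s, vals in per_sample.items()]


def alpha_frame(records: list[AlphaRecord]) -> pd.DataFrame:
    """Tidy sample x metric means from AlphaRecords."""
    rows = [
        {"sample_id": r.sample_id, "metric": r.metric, "mean": r.mean}
        for r in records
    ]
    return pd.DataFrame(rows).pivot(index="sample_id", columns="metric", values="mean")


def species_mean_alpha(records: list[AlphaRecord], metadata) -> pd.Series:
    """Average rarefied per-specimen values into one value per host
    species -- the unit of the between-species comparisons."""
    frame = pd.DataFrame(
        {"sample_id": [r.sample_id for r in records], "value": [r.mean for r in records]}
    ).set_index("sample_id")
    species = metadata.groups("host_species", frame.index)
    return frame["value"].groupby(species).mean()


def rarefaction_curve(
    table: OtuTable, depths, iterations: int = 10, seed_or_rng=0
) -> pd.DataFrame:
    """Mean observed OTU richness per sample at each depth.

    Depths above a sample's total reads give NaN for that sample.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    totals = table.sample_sums()
    out = pd.DataFrame(index=sorted(depths), columns=table.sample_ids, dtype=float)
    out.index.name = "depth"
    for depth in out.index:
        eligible = [s for s in table.sample_ids if totals[s] >= depth]
        if not eligible:
            continue
        acc = {s: [] for s in eligible}
        sub = table.select_samples(eligible)
        for _ in range(iterations):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rare = rarefy(sub, int(depth), rng)
            rich = (rare.data > 0).sum(axis=1)
            for s in eligible:
                acc[s].append(rich[s])
        for s in eligible:
            out.at[depth, s] = float(np.mean(acc[s]))
    return out
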