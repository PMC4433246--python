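"""Readers and writers for every on-disk format the pipeline touches.

Formats: tab-separated OTU tables (classic ``#OTU ID`` layout, OTUs as
rows), BIOM dense-JSON tables, two-column taxonomy TSV, sample-metadata
TSV, and Newick trees.  Every reader/writer pair is a lossless round
trip on valid input, and every reader validates before returning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .metadata import REQUIRED_COLUMNS, MetadataError, SampleMetadata
from .table import OtuTable, OtuTableError
from .taxonomy import TaxonomyMap, lineage_to_string, parse_lineage


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------

def read_otu_table(path, marker: str = "", metadata: SampleMetadata | None = None) -> OtuTable:
    """Read a TSV or BIOM dense-JSON OTU table.

    TSV layout is the classic one (rows = OTUs, columns = samples,
    first header cell ``#OTU ID``); the matrix is transposed to the
    in-memory samples x OTUs orientation.  When ``metadata`` is given,
    orientation is auto-detected by matching its sample ids against
    both axes; matching both (or neither) axis is an error, never a
    guess.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".biom" or path.suffix == ".json":
        return _read_biom_json(path, marker)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if metadata is not None:
        known = set(metadata.sample_ids)
        rows_match = bool(known.intersection(frame.index))
        cols_match = bool(known.intersection(frame.columns))
        if rows_match and cols_match:
            raise FormatError(
                f"{path}: sample ids found on both axes; orientation ambiguous"
            )
        if not rows_match and not cols_match:
            raise FormatError(f"{path}: no metadata sample id found on either axis")
        oriented = frame if rows_match else frame.T
    else:
        oriented = frame.T  # classic layout: OTU rows -> transpose
    try:
        return OtuTable(oriented, marker)
    except OtuTableError as exc:
        raise OtuTableError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path) -> None:
    """Write in the classic TSV layout (OTU rows x sample columns)."""
    out = table.data.T
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t", lineterminator="\n")


def _read_biom_json(path, marker: str) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise FormatError(f"{path}: only the dense BIOM JSON dialect is supported")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"])
    if data.shape != (len(otu_ids), len(sample_ids)):
        raise FormatError(f"{path}: BIOM data shape does not match row/column lists")
    frame = pd.DataFrame(data.T, index=sample_ids, columns=otu_ids)
    return OtuTable(frame, marker or doc.get("comment", ""))


def write_biom_json(table: OtuTable, path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "gutcore",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(table.otu_ids), len(table.sample_ids)],
        "comment": table.marker,
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.data.T.to_numpy().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


# ---------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------

def read_taxonomy(path) -> TaxonomyMap:
    """Two-column TSV: otu_id <tab> prefixed lineage string."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tax = TaxonomyMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            tax.set(parts[0], parse_lineage(parts[1]))
    return tax


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#OTU ID\ttaxonomy\n")
        for otu in tax:
            fh.write(f"{otu}\t{lineage_to_string(tax[otu])}\n")


# ---------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise MetadataError(f"{path}: missing metadata columns {missing}")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------

def read_tree(path, expected_tips=None) -> skbio.TreeNode:
    """Read a rooted Newick tree and validate it.

    Tip labels must be unique and branch lengths non-negative.  When
    ``expected_tips`` is given, every listed id must be a tip.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = skbio.TreeNode.read(str(path), format="newick")
    return validate_tree(tree, expected_tips)


def validate_tree(tree: skbio.TreeNode, expected_tips=None) -> skbio.TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        seen, dups = set(), set()
        for n in names:
            (dups if n in seen else seen).add(n)
        raise FormatError(f"duplicate tip labels: {sorted(dups)}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    if expected_tips is not None:
        missing = sorted(set(expected_tips) - set(names))
        if missing:
            raise FormatError(f"tree is missing tips: {missing}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree.write(str(path), format="newick")
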