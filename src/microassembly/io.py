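"""Reading and writing on-disk artifacts, bit-reproducibly.

All tabular formats are UTF-8 tab-separated values with '.' as the
decimal point regardless of locale; trees are Newick.  Count tables are
stored taxa-as-rows on disk (the amplicon convention); an orientation
flag handles transposed input.  Result tables are written with a
deterministic column order, a deterministic row sort and floats at 12
significant digits so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.io import NewickFormatError

from .containers import (
    CommunityTable,
    SampleMetadata,
    TaxonomyTable,
    validate_tree,
)

ORIENTATIONS = ("taxa_as_rows", "samples_as_rows")

#: significant digits for floats in result tables
FLOAT_FORMAT = "%.12g"


def _read_tsv(path) -> pd.DataFrame:
    # Read everything as strings first so duplicate/invalid cells can be
    # reported by position (pandas silently renames duplicate headers).
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = pd.Series(header[1:])
    if dupes.duplicated().any():
        raise ValueError(f"duplicate column id: {dupes[dupes.duplicated()].iloc[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    df.columns = header[1:]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id: {dup!r}")
    return df


def read_community_table(
    path, orientation: str = "taxa_as_rows", normalized: bool = False
) -> CommunityTable:
    """Read a TSV count table into a taxon-by-sample :class:`CommunityTable`.

    ``orientation`` declares how the file is laid out; the returned table
    is always taxon-by-sample.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    df = _read_tsv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "samples_as_rows":
        numeric = numeric.T
    return CommunityTable(numeric, is_normalized=normalized)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxon → ranked-lineage TSV (columns: taxon_id + ranks)."""
    df = _read_tsv(path)
    return TaxonomyTable(df)


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV (location, generation, mode, line)."""
    df = _read_tsv(path)
    return SampleMetadata(df)


def read_tree(path) -> TreeNode:
    """Read and validate a Newick phylogeny.

    Branch lengths must be present on every non-root node and be
    non-negative; the file must contain exactly one tree.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except NewickFormatError as exc:
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    return validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_biom_json(path, normalized: bool = False) -> CommunityTable:
    """Thin adapter for BIOM-style JSON (dense or sparse) count tables."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat, index=taxa, columns=samples)
    return CommunityTable(df, is_normalized=normalized)


def write_community_table(table: CommunityTable, path) -> None:
    """Write a count table taxa-as-rows; raw counts as integers."""
    df = table.counts
    if not table.is_normalized:
        df = df.round().astype(np.int64)
    df = df.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    df = taxonomy.lineage.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_tidy_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write one TSV per result table with a deterministic byte layout.

    Rows are sorted lexicographically over all columns, floats are
    rendered at 12 significant digits and the line terminator is fixed,
    so writing the same tables twice yields byte-identical files.
    Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        df = tables[name].reset_index(drop=True)
        if len(df):
            df = df.sort_values(list(df.columns), kind="mergesort")
        path = out_dir / f"{name}.tsv"
        df.to_csv(
            path,
            sep="\t",
            index=False,
            float_format=FLOAT_FORMAT,
            lineterminator="\n",
        )
        written.append(path)
    return written


def distance_matrix_to_long(dm) -> pd.DataFrame:
    """Flatten a DistanceMatrix-like object to (sample_i, sample_j, distance).

    Accepts a skbio DistanceMatrix or a square pandas DataFrame; emits
    one row per unordered pair (i < j in the matrix's own order).
    """
    if hasattr(dm, "ids"):
        ids = list(dm.ids)
        data = np.asarray(dm.data)
    else:
        ids = list(dm.index)
        data = dm.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], data[i, j]))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "distance"])
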