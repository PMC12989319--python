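"""Core in-memory containers shared by every pipeline stage.

The central object is the :class:`CommunityTable`, a taxon-by-sample count
matrix backed by a pandas DataFrame.  Trees are scikit-bio ``TreeNode``
objects and pairwise sample dissimilarities are scikit-bio
``DistanceMatrix`` objects; this module only adds the validation the
pipeline relies on (non-negativity, integrality of raw counts, unique
identifiers, branch lengths present and non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

#: Fixed rank order for taxonomy tables.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Generations recognised in sample metadata.
GENERATIONS = ("G1", "G2", "G3", "G4")

#: Reproductive modes recognised in sample metadata.
MODES = ("sexual", "asexual")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CommunityTable:
    """Taxon-by-sample abundance matrix.

    Parameters
    ----------
    counts
        DataFrame with taxa as the index and samples as the columns.
        Entries must be non-negative, and integral unless
        ``is_normalized`` is true.
    is_normalized
        Whether the entries are normalised abundances rather than raw
        read counts.
    """

    counts: pd.DataFrame
    is_normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "taxon")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("community table entries must be numeric")
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not self.is_normalized and not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"non-integer count at taxon {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r} in un-normalised table"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample library size (column sums)."""
        return self.counts.sum(axis=0)

    def select_taxa(self, taxa) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(taxa)], self.is_normalized)

    def select_samples(self, samples) -> "CommunityTable":
        return CommunityTable(self.counts[list(samples)], self.is_normalized)

    def drop_empty_taxa(self) -> tuple["CommunityTable", list[str]]:
        """Remove all-zero taxon rows; return (table, dropped taxon ids)."""
        keep = self.counts.sum(axis=1) > 0
        dropped = list(self.counts.index[~keep])
        return CommunityTable(self.counts.loc[keep], self.is_normalized), dropped


@dataclass
class TaxonomyTable:
    """Ranked lineage labels per taxon (domain … genus); blanks allowed."""

    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.lineage, pd.DataFrame):
            self.lineage = pd.DataFrame(self.lineage)
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"taxonomy table missing ranks: {missing}")
        _check_unique(self.lineage.index, "taxon")
        self.lineage = self.lineage[list(RANKS)].fillna("").astype(str)

    def labels_at(self, rank: str, taxa) -> pd.Series:
        """Labels at ``rank`` for ``taxa``; taxa absent from the table get ''."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineage[rank].reindex(taxa).fillna("")


@dataclass
class SampleMetadata:
    """Per-sample design variables: location, generation, mode, line."""

    table: pd.DataFrame

    required = ("location", "generation", "mode", "line")

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        missing = [c for c in self.required if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        _check_unique(self.table.index, "sample")
        bad_gen = set(self.table["generation"]) - set(GENERATIONS)
        if bad_gen:
            raise ValueError(f"unknown generation labels: {sorted(bad_gen)}")
        bad_mode = set(self.table["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown reproductive modes: {sorted(bad_mode)}")

    def require_samples(self, sample_ids) -> None:
        absent = [s for s in sample_ids if s not in self.table.index]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent[:5]}")

    def group_key(self, sample_ids, columns=("mode", "generation")) -> pd.Series:
        """Composite group label (e.g. ``asexual:G2``) per sample."""
        self.require_samples(sample_ids)
        sub = self.table.loc[list(sample_ids), list(columns)].astype(str)
        return sub.apply(lambda row: ":".join(row), axis=1)


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check tip uniqueness and branch lengths on a phylogeny.

    Branch lengths must be present and non-negative on every non-root
    node; nearest-taxon distances are meaningless without them.
    """
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            label = node.name or "<internal>"
            raise ValueError(f"branch length missing on node {label!r}")
        if node.length < 0:
            label = node.name or "<internal>"
            raise ValueError(f"negative branch length on node {label!r}")
    return tree
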