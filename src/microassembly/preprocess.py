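"""Dataset construction: taxonomy filters, rarefaction, TMM normalisation.

The stages mirror a standard amplicon workflow: remove contaminant
lineages (chloroplast, mitochondria, archaea, taxa uncharacterised at
the phylum level), exclude samples shallower than the rarefaction
threshold, rarefy every remaining sample to a common depth by
without-replacement subsampling, and compute trimmed-mean-of-M-values
(TMM) scaling factors for between-sample normalisation of the
un-rarefied track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import RANKS, CommunityTable, TaxonomyTable

#: Labels that match a blank lineage entry at the probed rank.
UNCHARACTERISED = {"uncharacterised", "uncharacterized"}

#: Contaminant-removal rules used by the default workflow.
DEFAULT_REMOVE_RULES = (
    ("order", "Chloroplast"),
    ("family", "Mitochondria"),
    ("domain", "Archaea"),
    ("phylum", "uncharacterised"),
)


@dataclass
class FilterSpec:
    """Taxonomy-based removal rules: (rank, label) pairs.

    Matching is case-insensitive and exact at the named rank; the label
    'uncharacterised' additionally matches taxa whose lineage is blank
    at that rank (including taxa absent from the taxonomy table, which
    are treated as uncharacterised at every rank).
    """

    remove_rules: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rank, _ in self.remove_rules:
            if rank not in RANKS:
                raise ValueError(
                    f"unknown rank {rank!r} in filter rule; expected one of {RANKS}"
                )


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors.

    ``table`` has one row per sample with columns ``lib_size``,
    ``factor`` and ``effective_lib_size`` (= lib_size × factor).  The
    factors are rescaled so their geometric mean is 1.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(self.table["factor"] <= 0):
            raise ValueError("TMM factors must be strictly positive")
        log_gm = np.log(self.table["factor"]).mean()
        if abs(log_gm) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def factors(self) -> pd.Series:
        return self.table["factor"]


def taxa_matching(
    table: CommunityTable, taxonomy: TaxonomyTable, rank: str, label: str
) -> list[str]:
    """Taxa in ``table`` whose lineage matches (rank, label), case-insensitively."""
    labels = taxonomy.labels_at(rank, table.taxon_ids)
    want = label.strip().lower()
    lowered = labels.str.strip().str.lower()
    hit = lowered == want
    if want in UNCHARACTERISED:
        hit |= lowered == ""
    return list(labels.index[hit.to_numpy()])


def filter_taxa(
    table: CommunityTable, taxonomy: TaxonomyTable, spec: FilterSpec
) -> tuple[CommunityTable, list[str]]:
    """Remove taxa matching any rule in ``spec``.

    Returns the filtered table (sample set unchanged) and the list of
    removed taxon ids.
    """
    removed: set[str] = set()
    for rank, label in spec.remove_rules:
        removed.update(taxa_matching(table, taxonomy, rank, label))
    keep = [t for t in table.taxon_ids if t not in removed]
    kept = CommunityTable(table.counts.loc[keep], table.is_normalized)
    return kept, sorted(removed)


def drop_shallow_samples(
    table: CommunityTable, min_depth: int
) -> tuple[CommunityTable, list[tuple[str, int]]]:
    """Exclude samples whose total reads fall below ``min_depth``.

    Samples at exactly the threshold are retained.  Returns the reduced
    table and the excluded (sample, depth) list; raises if nothing
    survives.
    """
    if table.is_normalized:
        raise ValueError("depth filtering applies to un-normalised counts")
    depths = table.depths()
    excluded = [
        (s, int(depths[s])) for s in table.sample_ids if depths[s] < min_depth
    ]
    keep = [s for s in table.sample_ids if depths[s] >= min_depth]
    if not keep:
        raise ValueError(f"all samples excluded at min_depth={min_depth}")
    return table.select_samples(keep), excluded


def rarefy(
    table: CommunityTable, depth: int, seed: int
) -> tuple[CommunityTable, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each column becomes a multivariate-hypergeometric draw from its
    observed reads; taxa left with all-zero rows are dropped and
    reported.  Deterministic given ``seed``.
    """
    if table.is_normalized:
        raise ValueError("rarefaction applies to raw counts")
    depths = table.depths()
    shallow = [s for s in table.sample_ids if depths[s] < depth]
    if shallow:
        raise ValueError(
            f"samples shallower than rarefaction depth {depth}: {shallow[:5]}"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().astype(np.int64)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    rarefied = CommunityTable(
        pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids)
    )
    return rarefied.drop_empty_taxa()


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference library.

    Log2 ratios of library-size-normalised counts (M) are trimmed by
    ``trim_m`` on each tail, average log2 abundances (A) by ``trim_a``
    on each tail, and the surviving M values are averaged with inverse
    approximate (delta-method) variances as weights.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValueError("no taxon shared with the reference sample")
    o, r = obs[shared].astype(float), ref[shared].astype(float)
    log_ratio = np.log2((o / n_obs) / (r / n_ref))
    abundance = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2.0
    weight = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = log_ratio.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_ratio)
    rank_a = rankdata(abundance)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / weight[keep]
    f = np.sum(log_ratio[keep] * inv_w) / np.sum(inv_w)
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    table: CommunityTable,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample.

    The reference defaults to the sample whose 75th-percentile
    count-to-library-size ratio is closest to the mean of those ratios.
    Factors are rescaled to geometric mean 1.
    """
    if table.is_normalized:
        raise ValueError("TMM factors are computed from raw counts")
    if table.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = table.counts.to_numpy().astype(float)
    lib_size = counts.sum(axis=0)
    if np.any(lib_size == 0):
        empty = table.sample_ids[int(np.argmin(lib_size))]
        raise ValueError(f"sample {empty!r} has zero reads")
    if ref_sample is None:
        uq = np.quantile(counts, 0.75, axis=0) / lib_size
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in table.sample_ids:
            raise ValueError(f"reference sample {ref_sample!r} not in table")
        ref_idx = table.sample_ids.index(ref_sample)
    ref = counts[:, ref_idx]
    factors = np.empty(table.n_samples)
    for j in range(table.n_samples):
        try:
            factors[j] = _tmm_pair_factor(counts[:, j], ref, trim_m, trim_a)
        except ValueError as exc:
            raise ValueError(
                f"sample {table.sample_ids[j]!r} vs reference "
                f"{table.sample_ids[ref_idx]!r}: {exc}"
            ) from exc
    factors /= np.exp(np.mean(np.log(factors)))
    out = pd.DataFrame(
        {
            "lib_size": lib_size,
            "factor": factors,
            "effective_lib_size": lib_size * factors,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    return NormalizationFactors(out)


def normalize(table: CommunityTable, factors: NormalizationFactors) -> CommunityTable:
    """Divide each sample by its effective library size (lib size × factor).

    Values are rescaled by the mean effective library size so the output
    stays on a reads-like scale.  The result is flagged normalised.
    """
    missing = [s for s in table.sample_ids if s not in factors.table.index]
    if missing:
        raise ValueError(f"no normalisation factor for samples: {missing[:5]}")
    lib_size = table.depths().to_numpy().astype(float)
    f = factors.factors.reindex(table.sample_ids).to_numpy()
    effective = lib_size * f
    scaled = table.counts.to_numpy() / effective * effective.mean()
    return CommunityTable(
        pd.DataFrame(scaled, index=table.taxon_ids, columns=table.sample_ids),
        is_normalized=True,
    )


def extract_taxon_counts(
    table: CommunityTable, taxonomy: TaxonomyTable, rank: str, label: str
) -> pd.Series:
    """Per-sample summed abundance of all taxa matching (rank, label).

    Samples with no matching taxa report 0; an absent label yields all
    zeros.
    """
    hits = taxa_matching(table, taxonomy, rank, label)
    if not hits:
        return pd.Series(
            0.0, index=pd.Index(table.sample_ids, name="sample_id"), name=label
        )
    summed = table.counts.loc[hits].sum(axis=0)
    summed.index.name = "sample_id"
    summed.name = label
    return summed
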