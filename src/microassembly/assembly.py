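"""Community-assembly null models: βMNTD → βNTI, Raup–Crick → RCbray.

The engine quantifies, for every sample pair, whether phylogenetic
turnover (β mean nearest taxon distance) and compositional turnover
(Bray–Curtis) deviate from randomised expectations, and partitions
pairs into five assembly processes:

* βNTI < −2  → homogeneous selection (less turnover than expected)
* βNTI > +2  → variable selection (more turnover than expected)
* otherwise, RCbray > +0.95 → dispersal limitation
*            RCbray < −0.95 → homogenising dispersal
*            |RCbray| ≤ 0.95 → undominated

The βNTI null shuffles the taxon↔tip assignment across the whole tree;
every null iteration yields the full pairwise βMNTD matrix, so all
pairs share each shuffle.  The Raup–Crick null assembles random
communities that preserve each sample's richness and read total, drawing
taxa with probability proportional to occupancy and allocating reads
proportionally to dataset-wide relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import CommunityTable, validate_tree

PROCESS_CLASSES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenising_dispersal",
    "undominated",
)

SELECTION_CLASSES = ("homogeneous_selection", "variable_selection")


@dataclass
class NullModelConfig:
    """Shared configuration of the randomisation machinery.

    ``n_null`` iterations (≥ 99; 999 by default), a master ``seed``,
    whether βMNTD is abundance weighted, and the absolute tolerance at
    which a null dissimilarity counts as tied with the observed one
    (ties get half weight in the Raup–Crick probability).
    """

    n_null: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    equality_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_null < 99:
            raise ValueError("n_null must be at least 99")


def patristic_distances(tree: TreeNode, taxa) -> DistanceMatrix:
    """Path-length (patristic) distance matrix over ``taxa``, in their order."""
    validate_tree(tree)
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa not found as tree tips: {missing[:5]}")
    return tree.tip_tip_distances(endpoints=list(taxa))


def _abundance_profile(table: CommunityTable, abundance_weighted: bool) -> np.ndarray:
    """Taxon-by-sample weight matrix: relative abundance or 1/richness."""
    counts = table.counts.to_numpy().astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        empty = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {empty!r} is an empty community")
    if abundance_weighted:
        return counts / totals
    presence = (counts > 0).astype(float)
    return presence / presence.sum(axis=0)


def _nearest_taxon_matrix(d: np.ndarray, support: list[np.ndarray]) -> np.ndarray:
    """dmin[i, s] = min over taxa j present in sample s of d[i, j]."""
    n_taxa = d.shape[0]
    dmin = np.empty((n_taxa, len(support)))
    for s, idx in enumerate(support):
        dmin[:, s] = d[:, idx].min(axis=1)
    return dmin


def _beta_mntd_from_parts(weights: np.ndarray, dmin: np.ndarray) -> np.ndarray:
    # one-sided sums: half[k, m] = Σ_i w_ik · dmin[i, m]; symmetrise
    half = weights.T @ dmin
    return 0.5 * (half + half.T)


def beta_mntd(
    table: CommunityTable,
    patristic: DistanceMatrix,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Abundance-weighted β mean nearest taxon distance between samples.

    βMNTD(k,m) = ½[Σ_{i∈k} f_ik·min_{j∈m} d_ij + Σ_{j∈m} f_jm·min_{i∈k} d_ij],
    with minima over taxa present in the other community; a taxon shared
    by both communities contributes distance 0.  The unweighted variant
    replaces the relative abundances f by 1/richness.
    """
    order = [t for t in patristic.ids if t in set(table.taxon_ids)]
    missing = set(table.taxon_ids) - set(patristic.ids)
    if missing:
        raise ValueError(
            f"taxa absent from patristic matrix: {sorted(missing)[:5]}"
        )
    sub = table.counts.loc[order]
    weights = _abundance_profile(
        CommunityTable(sub, table.is_normalized), abundance_weighted
    )
    d = np.asarray(patristic.filter(order).data, dtype=float)
    support = [np.flatnonzero(weights[:, s] > 0) for s in range(sub.shape[1])]
    dmin = _nearest_taxon_matrix(d, support)
    values = _beta_mntd_from_parts(weights, dmin)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix((values + values.T) / 2.0, ids=table.sample_ids)


@dataclass
class BetaNTIResult:
    """Observed βMNTD, null moments and βNTI per sample pair.

    Each field is a square sample-by-sample DataFrame.  ``bnti`` is NaN
    for pairs whose null standard deviation is 0 (degenerate nulls);
    such pairs are excluded from downstream summaries.
    """

    bmntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame


def beta_nti(
    table: CommunityTable,
    tree: TreeNode | DistanceMatrix,
    cfg: NullModelConfig,
) -> BetaNTIResult:
    """β nearest taxon index: deviation of βMNTD from a taxa-shuffle null.

    Each of ``cfg.n_null`` iterations permutes the taxon↔tip assignment
    (equivalently the rows/columns of the patristic matrix) and
    recomputes βMNTD for all pairs from the same shuffle.  βNTI(k,m) =
    (βMNTD_obs − mean_null)/sd_null with the n−1 standard deviation.
    Taxa are canonically sorted before drawing permutations, so results
    do not depend on input taxon order.  Deterministic given the seed.
    """
    # canonical taxon order: permutation draws are tied to sorted ids
    taxa = sorted(table.taxon_ids)
    sub = CommunityTable(table.counts.loc[taxa], table.is_normalized)
    if isinstance(tree, DistanceMatrix):
        patristic = tree.filter(taxa)
    else:
        patristic = patristic_distances(tree, taxa)
    d = np.asarray(patristic.data, dtype=float)
    weights = _abundance_profile(sub, cfg.abundance_weighted)
    support = [np.flatnonzero(weights[:, s] > 0) for s in range(sub.n_samples)]

    obs = _beta_mntd_from_parts(weights, _nearest_taxon_matrix(d, support))
    n = sub.n_samples
    rng = np.random.default_rng(cfg.seed)
    total = np.zeros((n, n))
    total_sq = np.zeros((n, n))
    n_taxa = len(taxa)
    for _ in range(cfg.n_null):
        perm = rng.permutation(n_taxa)
        d_null = d[np.ix_(perm, perm)]
        null = _beta_mntd_from_parts(
            weights, _nearest_taxon_matrix(d_null, support)
        )
        total += null
        total_sq += null**2
    mean = total / cfg.n_null
    var = (total_sq - cfg.n_null * mean**2) / (cfg.n_null - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / sd, np.nan)
    np.fill_diagonal(bnti, 0.0)
    degenerate = int(np.isnan(bnti[np.triu_indices(n, 1)]).sum())
    if degenerate:
        warnings.warn(
            f"{degenerate} sample pair(s) have zero null variance; "
            "βNTI reported as missing",
            stacklevel=2,
        )
    ids = pd.Index(sub.sample_ids, name="sample_id")

    def frame(x: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(x, index=ids, columns=ids)

    return BetaNTIResult(
        bmntd_obs=frame(obs), null_mean=frame(mean), null_sd=frame(sd),
        bnti=frame(bnti),
    )


def _null_bank(
    rng: np.random.Generator,
    n_null: int,
    richness: int,
    depth: int,
    log_occupancy: np.ndarray,
    abundance: np.ndarray,
) -> np.ndarray:
    """(n_null, n_taxa) random communities with fixed richness and depth.

    Taxa are drawn without replacement with probability proportional to
    occupancy (Gumbel top-k), seeded with one read each; the remaining
    reads are allocated multinomially with probability proportional to
    dataset-wide relative abundance among the drawn taxa.
    """
    n_taxa = log_occupancy.size
    if richness > n_taxa:
        raise ValueError(
            f"sample richness {richness} exceeds taxon pool size {n_taxa}"
        )
    gumbel = rng.gumbel(size=(n_null, n_taxa))
    keys = log_occupancy[None, :] + gumbel
    chosen = np.argpartition(keys, n_taxa - richness, axis=1)[:, n_taxa - richness:]
    # int16 suffices for rarefied read counts and sums promote to int64
    dtype = np.int16 if depth < np.iinfo(np.int16).max else np.int64
    bank = np.zeros((n_null, n_taxa), dtype=dtype)
    rows = np.repeat(np.arange(n_null), richness)
    bank[rows, chosen.ravel()] = 1
    extra = depth - richness
    if extra > 0:
        for i in range(n_null):
            p = abundance[chosen[i]]
            bank[i, chosen[i]] += rng.multinomial(extra, p / p.sum())
    return bank


def raup_crick_bray(
    table: CommunityTable,
    cfg: NullModelConfig,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Bray–Curtis-based Raup–Crick metric per sample pair, in [−1, 1].

    For each pair, ``cfg.n_null`` pairs of null communities are built
    (each preserving its sample's observed richness and read total) and
    compared by Bray–Curtis.  With p the fraction of null dissimilarities
    below the observed one (ties at ``cfg.equality_tolerance`` counting
    half), RCbray = 2·(p − ½).  Null communities are drawn per distinct
    (richness, depth) combination from two independent banks shared
    across pairs, so the per-pair null distribution is unaffected while
    the whole table costs one bank per combination.  Deterministic given
    the seed; symmetric by construction.

    ``pairs`` restricts computation to the listed sample pairs (default:
    all pairs).  Returns a square DataFrame with NaN for uncomputed
    pairs and 0 on the diagonal.
    """
    if table.is_normalized:
        raise ValueError("Raup–Crick requires integer (rarefied) counts")
    if table.n_samples < 2:
        raise ValueError("Raup–Crick needs at least 2 samples")
    taxa = sorted(table.taxon_ids)
    counts = table.counts.loc[taxa].to_numpy().astype(np.int64)
    sample_ids = table.sample_ids
    presence = counts > 0
    occupancy = presence.sum(axis=1).astype(float)
    occupancy = occupancy / presence.shape[1]
    abundance = counts.sum(axis=1).astype(float)
    abundance /= abundance.sum()
    # taxa never observed cannot be drawn; give them -inf keys
    with np.errstate(divide="ignore"):
        log_occ = np.log(occupancy)

    richness = presence.sum(axis=0)
    depth = counts.sum(axis=0)
    if np.any(richness == 0):
        empty = sample_ids[int(np.argmin(richness))]
        raise ValueError(f"sample {empty!r} is an empty community")

    if pairs is None:
        pair_idx = [
            (i, j)
            for i in range(len(sample_ids))
            for j in range(i + 1, len(sample_ids))
        ]
    else:
        pos = {s: i for i, s in enumerate(sample_ids)}
        pair_idx = []
        for a, b in pairs:
            if a not in pos or b not in pos:
                raise ValueError(f"unknown sample in pair ({a!r}, {b!r})")
            i, j = pos[a], pos[b]
            pair_idx.append((min(i, j), max(i, j)))

    banks: dict[tuple[int, int, int], np.ndarray] = {}

    def bank_for(side: int, r: int, n: int) -> np.ndarray:
        key = (side, r, n)
        if key not in banks:
            seq = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(side, r, n)
            )
            banks[key] = _null_bank(
                np.random.default_rng(seq), cfg.n_null, r, n, log_occ, abundance
            )
        return banks[key]

    obs_bc = np.full((len(sample_ids), len(sample_ids)), np.nan)
    rc = np.full_like(obs_bc, np.nan)
    np.fill_diagonal(rc, 0.0)
    for i, j in pair_idx:
        u, v = counts[:, i].astype(float), counts[:, j].astype(float)
        obs = np.abs(u - v).sum() / (u + v).sum()
        bank_i = bank_for(0, int(richness[i]), int(depth[i]))
        bank_j = bank_for(1, int(richness[j]), int(depth[j]))
        null = np.abs(bank_i - bank_j).sum(axis=1) / (bank_i + bank_j).sum(axis=1)
        below = np.sum(null < obs - cfg.equality_tolerance)
        ties = np.sum(np.abs(null - obs) <= cfg.equality_tolerance)
        p = (below + 0.5 * ties) / cfg.n_null
        rc[i, j] = rc[j, i] = 2.0 * (p - 0.5)
        obs_bc[i, j] = obs_bc[j, i] = obs
    ids = pd.Index(sample_ids, name="sample_id")
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_pair(bnti: float, rc: float | None = None) -> str:
    """Assign the five-way assembly-process class from βNTI and RCbray.

    Selection classes are decided by βNTI alone (thresholds ±2); inside
    the stochastic band the Raup–Crick value decides (thresholds ±0.95).
    ``rc`` may be omitted only when |βNTI| > 2.
    """
    if not np.isfinite(bnti):
        raise ValueError("βNTI must be finite to classify a pair")
    if bnti < -2:
        return "homogeneous_selection"
    if bnti > 2:
        return "variable_selection"
    if rc is None or not np.isfinite(rc):
        raise ValueError("RCbray required when |βNTI| ≤ 2")
    if not -1.0 - 1e-12 <= rc <= 1.0 + 1e-12:
        raise ValueError(f"RCbray out of range [-1, 1]: {rc}")
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenising_dispersal"
    return "undominated"


def build_pair_table(
    nti: BetaNTIResult,
    rc: pd.DataFrame,
    groups: pd.Series,
    within_groups_only: bool = True,
) -> pd.DataFrame:
    """Per-pair record: βMNTD, null moments, βNTI, RCbray, process, group.

    ``groups`` maps sample id → group key (e.g. mode:generation).  By
    default only within-group pairs are kept, matching per-group process
    summaries; pass ``within_groups_only=False`` for all pairs (the
    group column then holds 'i-group|j-group' for cross-group pairs).
    Pairs with missing βNTI (degenerate null) are dropped with a warning.
    """
    ids = list(nti.bnti.index)
    rows = []
    n_missing = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            si, sj = ids[i], ids[j]
            gi, gj = groups[si], groups[sj]
            if within_groups_only and gi != gj:
                continue
            bnti = nti.bnti.iat[i, j]
            if not np.isfinite(bnti):
                n_missing += 1
                continue
            rc_val = rc.at[si, sj] if si in rc.index and sj in rc.columns else np.nan
            process = classify_pair(
                bnti, None if not np.isfinite(rc_val) else rc_val
            )
            rows.append(
                {
                    "sample_i": si,
                    "sample_j": sj,
                    "group": gi if gi == gj else f"{gi}|{gj}",
                    "bmntd_obs": nti.bmntd_obs.iat[i, j],
                    "null_mean": nti.null_mean.iat[i, j],
                    "null_sd": nti.null_sd.iat[i, j],
                    "bnti": bnti,
                    "rc": rc_val,
                    "process": process,
                }
            )
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} pair(s) with undefined βNTI", stacklevel=2
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_i", "sample_j", "group", "bmntd_obs", "null_mean",
            "null_sd", "bnti", "rc", "process",
        ],
    )


def summarize_processes(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of pairs per assembly-process class, per group.

    Classes absent from a group are reported as 0; groups with no pairs
    are omitted (a warning is raised if the input is entirely empty).
    """
    if pair_table.empty:
        warnings.warn("no pairs to summarise", stacklevel=2)
        return pd.DataFrame(
            columns=["group", "n_pairs", *PROCESS_CLASSES]
        )
    rows = []
    for group, sub in pair_table.groupby("group", sort=True):
        frac = sub["process"].value_counts(normalize=True)
        row = {"group": group, "n_pairs": int(len(sub))}
        for cls in PROCESS_CLASSES:
            row[cls] = float(frac.get(cls, 0.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "n_pairs", *PROCESS_CLASSES])
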