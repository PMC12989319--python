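"""Alpha and beta diversity: richness/Shannon, Bray–Curtis, PCoA, PERMANOVA.

PCoA and PERMANOVA are implemented directly on the distance matrix
(classical multidimensional scaling of the Gower-centred squared
distances, and the pseudo-F permutation test on label shuffles); the
scikit-bio implementations serve as independent cross-checks in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import CommunityTable


def alpha_diversity(table: CommunityTable, base: float = np.e) -> pd.DataFrame:
    """Observed taxon count and Shannon diversity per sample.

    Shannon is −Σ pᵢ log pᵢ over non-zero relative abundances, in nats
    by default (``base`` configurable).  Raises on an all-zero sample.
    """
    counts = table.counts.to_numpy().astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        empty = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {empty!r} has zero total abundance")
    observed = (counts > 0).sum(axis=0)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0) / np.log(base)
    return pd.DataFrame(
        {"observed_asv": observed.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    d(k,m) = 1 − 2·Σ min(xᵢₖ, xᵢₘ) / (Σ xᵢₖ + Σ xᵢₘ).
    """
    if table.n_samples < 2:
        raise ValueError("Bray–Curtis needs at least 2 samples")
    counts = table.counts.to_numpy().astype(float).T
    if np.any(counts.sum(axis=1) == 0):
        empty = table.sample_ids[int(np.argmin(counts.sum(axis=1)))]
        raise ValueError(f"sample {empty!r} has zero total abundance")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class Ordination:
    """Principal-coordinates embedding of a distance matrix.

    Axes with positive eigenvalues only, ordered by decreasing
    eigenvalue; ``proportion_explained`` is relative to the sum of
    positive eigenvalues.  Negative eigenvalues (non-Euclidean input)
    are counted but their axes are omitted, and no correction is
    applied.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical (metric) multidimensional scaling of ``dm``."""
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("PCoA requires a symmetric square distance matrix")
    n = d.shape[0]
    a = -0.5 * d**2
    centred = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centred)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    n_negative = int((eigvals < -tol).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    ids = list(getattr(dm, "ids", range(n)))
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=pd.Index(ids, name="sample_id"), columns=axes
        ),
        eigenvalues=eigvals,
        proportion_explained=lam / lam.sum(),
        n_negative_eigenvalues=n_negative,
    )


@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    term: str = "group",
) -> PermanovaResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    Pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)) with sums of
    squares computed from squared dissimilarities; the p-value counts
    label permutations whose F is at least the observed, with the
    observed arrangement included, so it is never 0.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    labels = np.asarray(pd.Series(grouping).astype(str))
    if labels.size != n:
        raise ValueError("grouping length does not match distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if a >= n:
        raise ValueError("every sample in its own group leaves no residual df")
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_between = ss_total - ss_within

    def f_stat(ss_w: float) -> float:
        # ss_w = 0 (duplicated points within groups) gives F = inf
        with np.errstate(divide="ignore"):
            return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if f_stat(_ss_within(d2, perm, a)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        term=term,
        pseudo_f=float(f_obs),
        r2=float(ss_between / ss_total),
        p_value=float(p),
        n_permutations=n_permutations,
        df_between=a - 1,
        df_within=n - a,
    )


def permanova_terms(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run a separate one-way PERMANOVA per metadata column.

    Returns a tidy table with one row per term.
    """
    ids = list(dm.ids)
    rows = []
    for k, t in enumerate(terms):
        res = permanova(
            dm,
            metadata.loc[ids, t],
            n_permutations=n_permutations,
            seed=None if seed is None else seed + k,
            term=t,
        )
        rows.append(
            {
                "term": res.term,
                "pseudo_f": res.pseudo_f,
                "r2": res.r2,
                "p_value": res.p_value,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)
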