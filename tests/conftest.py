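import numpy as np
import pandas as pd
import pytest

from microassembly import (
    CommunityTable,
    TaxonomyTable,
    simulate_tree,
)


@pytest.fixture
def tiny_table() -> CommunityTable:
    """3 taxa × 2 samples, integer counts."""
    return CommunityTable(
        pd.DataFrame(
            {"s1": [5, 3, 0], "s2": [1, 0, 7]},
            index=["taxA", "taxB", "taxC"],
        )
    )


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    rows = {
        "taxA": ["Bacteria", "Proteobacteria", "Alpha", "Rickettsiales",
                 "Anaplasmataceae", "Wolbachia"],
        "taxB": ["Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                 "Bacillaceae", "Bacillus"],
        "taxC": ["Bacteria", "", "", "", "", ""],
        "taxD": ["Archaea", "Crenarchaeota", "", "", "", ""],
        "taxE": ["Bacteria", "Cyanobacteria", "Cyanobacteriia",
                 "Chloroplast", "", ""],
    }
    return TaxonomyTable(
        pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["domain", "phylum", "class", "order", "family", "genus"],
        )
    )


def random_community(rng: np.random.Generator, n_taxa: int, n_samples: int,
                     max_count: int = 50) -> CommunityTable:
    """Random sparse integer community; every sample non-empty."""
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts[rng.random((n_taxa, n_samples)) < 0.4] = 0
    for s in range(n_samples):
        if counts[:, s].sum() == 0:
            counts[rng.integers(n_taxa), s] = 1 + rng.integers(max_count)
    taxa = [f"t{i:03d}" for i in range(n_taxa)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return CommunityTable(pd.DataFrame(counts, index=taxa, columns=samples))


def brute_force_beta_mntd(table: CommunityTable, dist: np.ndarray,
                          abundance_weighted: bool = True) -> np.ndarray:
    """Independent double-loop βMNTD evaluation (taxa in table order)."""
    counts = table.counts.to_numpy().astype(float)
    n = counts.shape[1]
    out = np.zeros((n, n))
    freq = counts / counts.sum(axis=0)
    for k in range(n):
        for m in range(n):
            if k == m:
                continue
            in_k = np.flatnonzero(counts[:, k] > 0)
            in_m = np.flatnonzero(counts[:, m] > 0)
            if abundance_weighted:
                wk = freq[in_k, k]
                wm = freq[in_m, m]
            else:
                wk = np.full(in_k.size, 1.0 / in_k.size)
                wm = np.full(in_m.size, 1.0 / in_m.size)
            s1 = sum(
                w * min(dist[i, j] for j in in_m) for i, w in zip(in_k, wk)
            )
            s2 = sum(
                w * min(dist[i, j] for i in in_k) for j, w in zip(in_m, wm)
            )
            out[k, m] = 0.5 * (s1 + s2)
    return out


@pytest.fixture
def random_tree():
    return simulate_tree(12, seed=7)
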