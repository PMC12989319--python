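"""Synthetic study-shaped fixtures: tree, traits, taxonomy, communities.

The generator emulates the shape of a longitudinal host-microbiome
survey — replicate iso-female lines from several locations sampled over
four generations, read depths straddling a rarefaction threshold, and a
dominant maternally inherited endosymbiont (genus *Wolbachia*) in the
asexual locations — under known assembly regimes so that process
recovery can be scored against ground truth.

Each regime is a generative recipe targeting the construct the
classifier measures, not a claim about any real host system:

* ``homogeneous_selection`` — every sample filters the species pool
  around the same trait optimum (phylogenetically conserved trait), so
  phylogenetic turnover is lower than the taxa-shuffle null.
* ``variable_selection`` — samples filter around strongly different
  optima, so turnover is higher than the null.
* ``dispersal_limitation`` — no selection; each sample drifts to its own
  dominant taxa, so compositional turnover exceeds the Raup–Crick null.
* ``homogenising_dispersal`` — all samples are multinomial resamples of
  one common source pool, so turnover falls below the Raup–Crick null.
* ``neutral`` — independent lognormal noise around a shared baseline,
  calibrated to sit inside both null envelopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, SampleMetadata, TaxonomyTable
from . import io as mio

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenising_dispersal",
    "neutral",
)

PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidota", "Actinobacteriota")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic assembly scenario.

    Defaults describe a desk-scale community: 80 taxa, 12 samples,
    2000 reads per sample.  ``selection_strength`` is the width (in
    trait standard deviations) of the Gaussian environmental filter;
    ``trait_signal`` the Brownian rate of trait evolution;
    ``noise_sdlog`` the per-sample lognormal abundance noise (raised to
    ``drift_sdlog`` under dispersal limitation); ``migration_rate`` the
    share of the common pool mixed into every sample.  The endosymbiont
    is injected into ``endosymbiont_fraction`` of the samples at an
    expected relative abundance of ``endosymbiont_share``.
    """

    regime: str = "neutral"
    n_taxa: int = 80
    n_clades: int = 1
    clade_depth: float = 1.0
    n_samples: int = 12
    read_depth_mean: float = 2000.0
    read_depth_sigma: float = 0.0
    selection_strength: float = 0.35
    trait_signal: float = 1.0
    migration_rate: float = 0.0
    baseline_sdlog: float = 1.0
    noise_sdlog: float = 1.0
    drift_sdlog: float = 3.0
    occupancy: float = 0.6
    env_levels: int = 3
    endosymbiont_fraction: float = 0.0
    endosymbiont_share: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        for name in (
            "read_depth_mean", "trait_signal", "migration_rate",
            "baseline_sdlog", "noise_sdlog", "drift_sdlog",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.endosymbiont_share < 1:
            raise ValueError("endosymbiont_share must be in [0, 1)")
        if not 0 <= self.endosymbiont_fraction <= 1:
            raise ValueError("endosymbiont_fraction must be in [0, 1]")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        if (
            self.regime in ("homogeneous_selection", "variable_selection")
            and self.selection_strength <= 0
        ):
            raise ValueError("selection regimes need selection_strength > 0")


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus the generating truth."""

    table: CommunityTable
    taxonomy: TaxonomyTable
    tree: TreeNode
    metadata: SampleMetadata
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        """Write all members as the text formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out / "counts.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "metadata": out / "metadata.tsv",
            "tree": out / "tree.nwk",
            "truth": out / "truth.json",
        }
        mio.write_community_table(self.table, paths["counts"])
        mio.write_taxonomy(self.taxonomy, paths["taxonomy"])
        mio.write_metadata(self.metadata, paths["metadata"])
        mio.write_tree(self.tree, paths["tree"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _yule(n_tips: int, rng: np.random.Generator, birth_rate: float) -> TreeNode:
    """Unnamed pure-birth tree: every lineage splits at ``birth_rate``."""
    root = TreeNode(name=None, length=None)
    if n_tips == 1:
        root.extend([TreeNode(length=rng.exponential(1.0 / birth_rate))])
        return root
    first = [TreeNode(length=0.0), TreeNode(length=0.0)]
    root.extend(first)
    active = list(first)
    while True:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        if len(active) == n_tips:
            break
        parent = active.pop(rng.integers(len(active)))
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(children)
        active.extend(children)
    return root


def simulate_tree(
    n_taxa: int,
    seed: int,
    birth_rate: float = 1.0,
    n_clades: int = 1,
    stem_length: float = 4.0,
    clade_depth: float = 1.0,
) -> TreeNode:
    """Pure-birth (Yule) tree with exponential inter-split times.

    With ``n_clades > 1`` the taxa radiate as that many independent
    pure-birth clades (each rescaled to unit depth) hanging from long
    stem branches, so Brownian traits evolve clade-level structure —
    deep conservation within clades, strong divergence between them —
    which is the situation in which nearest-taxon phylogenetic metrics
    are informative.  Tips are labelled ``ASV_0001`` … in traversal
    order; deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    if n_clades <= 1:
        root = _yule(n_taxa, rng, birth_rate)
    else:
        if n_clades > n_taxa:
            raise ValueError("more clades than taxa")
        sizes = np.full(n_clades, n_taxa // n_clades)
        sizes[: n_taxa % n_clades] += 1
        root = TreeNode(name=None, length=None)
        for size in sizes:
            clade = _yule(int(size), rng, birth_rate)
            depth = max(
                sum(a.length for a in tip.ancestors() if a.length) + tip.length
                for tip in clade.tips()
            )
            for node in clade.traverse(include_self=False):
                node.length *= clade_depth / depth
            clade.length = stem_length * (0.75 + rng.exponential(0.25))
            root.extend([clade])
    for k, tip in enumerate(root.tips(), start=1):
        tip.name = f"ASV_{k:04d}"
    return root


def evolve_trait(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Brownian trait along branches from a root value of 0.

    The increment on a branch of length L has variance rate·L, so the
    difference between two cherry tips with branch lengths L has
    variance 2·rate·L.  Returns one value per tip.
    """
    if rate < 0:
        raise ValueError("Brownian rate must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    traits = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(rate * (node.length or 0.0)))
        values[id(node)] = parent_val + step
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return pd.Series({t.name: traits[t.name] for t in tree.tips()}, name="trait")


def default_taxonomy(
    taxa: list[str],
    seed: int,
    symbiont_taxa: tuple[str, ...] = (),
    contaminants: dict[str, str] | None = None,
) -> TaxonomyTable:
    """Plausible ranked lineages for synthetic taxa.

    ``symbiont_taxa`` get genus *Wolbachia*; ``contaminants`` maps taxon
    id → kind in {'chloroplast', 'mitochondria', 'archaea',
    'unknown_phylum'} and produces the matching removable lineages.
    """
    rng = np.random.default_rng(seed)
    contaminants = contaminants or {}
    rows = []
    for t in taxa:
        phylum = PHYLA[rng.integers(len(PHYLA))]
        row = {
            "domain": "Bacteria",
            "phylum": phylum,
            "class": f"{phylum}_class",
            "order": f"Order_{t[-3:]}",
            "family": f"Family_{t[-3:]}",
            "genus": f"Genus_{t[-4:]}",
        }
        kind = contaminants.get(t)
        if kind == "chloroplast":
            row.update(phylum="Cyanobacteria", order="Chloroplast")
            row["class"] = "Cyanobacteriia"
        elif kind == "mitochondria":
            row.update(order="Rickettsiales", family="Mitochondria")
        elif kind == "archaea":
            row.update(domain="Archaea", phylum="Crenarchaeota")
        elif kind == "unknown_phylum":
            row.update(phylum="", **{"class": "", "order": "", "family": "", "genus": ""})
        if t in symbiont_taxa:
            row.update(
                phylum="Proteobacteria",
                order="Rickettsiales",
                family="Anaplasmataceae",
                genus="Wolbachia",
            )
            row["class"] = "Alphaproteobacteria"
        rows.append(row)
    return TaxonomyTable(pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id")))


def _standardized(traits: pd.Series) -> np.ndarray:
    z = traits.to_numpy()
    return (z - z.mean()) / z.std()


def _regime_weights(
    regime: str,
    z: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    n_samples: int,
) -> tuple[np.ndarray, dict]:
    """Expected-abundance weight matrix (taxa × samples) plus truth extras."""
    n_taxa = z.size
    baseline = rng.normal(0.0, cfg.baseline_sdlog, n_taxa)
    pool = np.exp(baseline)
    extras: dict = {}
    # selection optima are anchored at traits of actual tips, so every
    # optimum has a phylogenetic neighbourhood of similar-trait taxa
    if regime == "homogeneous_selection":
        anchor = int(np.argmin(np.abs(z - np.median(z))))
        env = np.full(n_samples, z[anchor])
    elif regime == "variable_selection":
        order = np.argsort(z)
        quantiles = np.linspace(0.05, 0.95, max(2, cfg.env_levels))
        quantile_tips = order[[int(q * (n_taxa - 1)) for q in quantiles]]
        levels = z[quantile_tips]
        env = levels[np.arange(n_samples) % levels.size]
    else:
        env = np.full(n_samples, np.nan)
    extras["env"] = [None if not np.isfinite(e) else float(e) for e in env]

    weights = np.empty((n_taxa, n_samples))
    if regime == "homogenising_dispersal":
        shared = np.exp(baseline + rng.normal(0.0, cfg.noise_sdlog, n_taxa))
        weights[:] = shared[:, None]
    else:
        noise_sd = (
            cfg.drift_sdlog if regime == "dispersal_limitation" else cfg.noise_sdlog
        )
        for s in range(n_samples):
            w = np.exp(baseline + rng.normal(0.0, noise_sd, n_taxa))
            if regime in ("homogeneous_selection", "variable_selection"):
                filt = np.exp(-((z - env[s]) ** 2) / (2 * cfg.selection_strength**2))
                w = w * filt
            if cfg.migration_rate > 0:
                pool_p = pool / pool.sum()
                w = (1 - cfg.migration_rate) * w / w.sum() + cfg.migration_rate * pool_p
            # per-sample occupancy thinning: ASV tables are sparse, and the
            # nearest-taxon metrics are only informative when communities
            # do not all contain the whole species pool
            if cfg.occupancy < 1:
                present = rng.random(n_taxa) < cfg.occupancy
                if present.sum() < 2:
                    present[np.argsort(w)[-2:]] = True
                w = np.where(present, w, 0.0)
            weights[:, s] = w
    return weights / weights.sum(axis=0), extras


def _draw_counts(
    weights: np.ndarray,
    depths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    counts = np.empty(weights.shape, dtype=np.int64)
    for s in range(weights.shape[1]):
        counts[:, s] = rng.multinomial(int(depths[s]), weights[:, s])
    return counts


def _sample_depths(cfg: ScenarioConfig, rng, n_samples: int) -> np.ndarray:
    if cfg.read_depth_sigma == 0:
        return np.full(n_samples, int(round(cfg.read_depth_mean)))
    mu = np.log(cfg.read_depth_mean) - cfg.read_depth_sigma**2 / 2
    return np.maximum(
        1, np.round(rng.lognormal(mu, cfg.read_depth_sigma, n_samples))
    ).astype(np.int64)


def assemble_communities(
    tree: TreeNode,
    traits: pd.Series,
    cfg: ScenarioConfig,
    sample_ids: list[str] | None = None,
    symbiont_samples: list[str] | None = None,
) -> FixtureBundle:
    """Assemble a count table under ``cfg.regime`` over the given tree.

    Expected relative abundances combine a shared lognormal baseline,
    regime-specific environmental filtering / drift / pool sharing, and
    multinomial read sampling at each sample's depth.  The last two tips
    of the tree act as the endosymbiont ASVs (genus *Wolbachia*) when an
    endosymbiont share is configured; designated samples receive it at
    the configured expected relative abundance, split 4:1 between the
    two ASVs.
    """
    taxa = [t.name for t in tree.tips()]
    if list(traits.index) != taxa:
        traits = traits.reindex(taxa)
        if traits.isna().any():
            raise ValueError("traits missing for some tree tips")
    if sample_ids is None:
        sample_ids = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    n_samples = len(sample_ids)
    rng = np.random.default_rng(cfg.seed)
    z = _standardized(traits)

    symbiont_taxa: tuple[str, ...] = ()
    use_symbiont = cfg.endosymbiont_share > 0 and (
        cfg.endosymbiont_fraction > 0 or symbiont_samples is not None
    )
    if use_symbiont:
        symbiont_taxa = tuple(taxa[-2:])
        if len(taxa) < 4:
            raise ValueError("endosymbiont injection needs at least 4 taxa")
    host_taxa_mask = np.array([t not in symbiont_taxa for t in taxa])

    weights, extras = _regime_weights(cfg.regime, z, cfg, rng, n_samples)
    if use_symbiont:
        if symbiont_samples is None:
            n_carrier = int(round(cfg.endosymbiont_fraction * n_samples))
            symbiont_samples = list(sample_ids[:n_carrier])
        carrier = np.array([s in set(symbiont_samples) for s in sample_ids])
        weights[~host_taxa_mask, :] = 0.0
        weights = weights / weights.sum(axis=0)
        share = cfg.endosymbiont_share
        for s in np.flatnonzero(carrier):
            weights[:, s] *= 1.0 - share
            weights[-2, s] = share * 0.8
            weights[-1, s] = share * 0.2
    else:
        symbiont_samples = []

    depths = _sample_depths(cfg, rng, n_samples)
    counts = _draw_counts(weights, depths, rng)
    # a sample must not be empty; with any positive depth this is a.s. fine
    table = CommunityTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=sample_ids)
    )
    taxonomy = default_taxonomy(taxa, seed=cfg.seed + 7, symbiont_taxa=symbiont_taxa)
    meta = pd.DataFrame(
        {
            "location": "L1",
            "generation": "G1",
            "mode": ["asexual" if s in set(symbiont_samples) else "sexual" for s in sample_ids],
            "line": [str(j % 7 + 1) for j in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {
        "regime": cfg.regime,
        "config": asdict(cfg),
        "symbiont_samples": sorted(symbiont_samples),
        "symbiont_taxa": list(symbiont_taxa),
        **extras,
    }
    return FixtureBundle(table, taxonomy, tree, SampleMetadata(meta), truth)


def simulate_scenario(cfg: ScenarioConfig) -> FixtureBundle:
    """One-call scenario fixture: tree + Brownian trait + communities."""
    tree = simulate_tree(
        cfg.n_taxa, seed=cfg.seed, n_clades=cfg.n_clades,
        clade_depth=cfg.clade_depth,
    )
    traits = evolve_trait(tree, rate=max(cfg.trait_signal, 1e-12), seed=cfg.seed + 1)
    return assemble_communities(tree, traits, cfg)


#: Per-regime generator parameters used for process-recovery scoring.
#: Selection regimes use a 200-taxon pool of many small, shallow clades
#: (so the trait filter admits whole clades and per-sample tip thinning
#: produces within-clade turnover), a narrow filter and flat abundances;
#: dispersal limitation uses strong independent per-sample drift over a
#: broadly shared species pool; homogenising dispersal resamples one
#: heavy-tailed shared pool.
RECOVERY_PARAMS: dict[str, dict] = {
    "homogeneous_selection": dict(
        n_taxa=200, n_clades=50, clade_depth=0.1, occupancy=0.7,
        selection_strength=0.10, baseline_sdlog=0.5, noise_sdlog=0.25,
    ),
    "variable_selection": dict(
        n_taxa=200, n_clades=50, clade_depth=0.1, occupancy=0.7,
        selection_strength=0.10, baseline_sdlog=0.5, noise_sdlog=0.25,
        env_levels=4,
    ),
    "dispersal_limitation": dict(
        n_taxa=200, n_clades=10, occupancy=0.4, drift_sdlog=3.0,
    ),
    "homogenising_dispersal": dict(
        n_taxa=200, n_clades=10, noise_sdlog=2.0,
    ),
    "neutral": dict(n_taxa=200, n_clades=10, occupancy=0.4),
}


def recovery_scenario(regime: str, seed: int, n_samples: int = 12) -> ScenarioConfig:
    """Scenario config at the documented per-regime recovery parameters."""
    if regime not in RECOVERY_PARAMS:
        raise ValueError(f"unknown regime {regime!r}")
    return ScenarioConfig(
        regime=regime, seed=seed, n_samples=n_samples, **RECOVERY_PARAMS[regime]
    )


#: Per-regime generator parameters at the 900-taxon study scale: sparser
#: per-sample occupancy than the recovery scenarios (ASV tables of whole
#: insects are sparse) while keeping each regime's defining mechanism.
STUDY_PARAMS: dict[str, dict] = {
    "homogeneous_selection": dict(
        occupancy=0.10, selection_strength=0.15, baseline_sdlog=0.5,
        noise_sdlog=0.5,
    ),
    "variable_selection": dict(
        occupancy=0.10, selection_strength=0.15, baseline_sdlog=0.5,
        noise_sdlog=0.5, env_levels=4,
    ),
    "dispersal_limitation": dict(occupancy=0.4, drift_sdlog=3.0),
    "homogenising_dispersal": dict(noise_sdlog=2.0),
    "neutral": dict(occupancy=0.10),
}

#: regime of each reproductive-mode × generation group in the study fixture;
#: echoes the study narrative (early selection, asexual homogenisation,
#: sexual dispersal limitation in later generations).
STUDY_GROUP_REGIMES = {
    ("asexual", "G1"): "homogeneous_selection",
    ("asexual", "G2"): "neutral",
    ("asexual", "G3"): "homogenising_dispersal",
    ("asexual", "G4"): "homogenising_dispersal",
    ("sexual", "G1"): "homogeneous_selection",
    ("sexual", "G2"): "neutral",
    ("sexual", "G3"): "dispersal_limitation",
    ("sexual", "G4"): "dispersal_limitation",
}


def generate_study_fixture(
    seed: int,
    n_taxa: int = 900,
    n_clades: int = 30,
    depth_mean: float = 3000.0,
    depth_sigma: float = 0.45,
    endosymbiont_share: float = 0.55,
    n_core_taxa: int = 60,
    core_share: float = 0.3,
) -> FixtureBundle:
    """Full 168-sample study-shaped fixture.

    Six locations (3 sexual, 3 asexual) × 7 replicate lines × 4
    generations; asexual-location samples carry the endosymbiont
    (2 *Wolbachia* ASVs at an expected joint share of
    ``endosymbiont_share``); lognormal read depths leave a few samples
    below the 1196-read rarefaction threshold; a small set of
    contaminant lineages (chloroplast, mitochondria, archaea,
    phylum-level uncharacterised) exercises taxonomy filtering.  Each
    mode × generation group is assembled under the regime in
    ``STUDY_GROUP_REGIMES``; the truth record stores the mapping.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed, n_clades=n_clades)
    traits = evolve_trait(tree, rate=1.0, seed=seed + 1)
    taxa = [t.name for t in tree.tips()]
    symbiont_taxa = tuple(taxa[-2:])

    locations = {
        "S1": "sexual", "S2": "sexual", "S3": "sexual",
        "A1": "asexual", "A2": "asexual", "A3": "asexual",
    }
    records = []
    for loc, mode in locations.items():
        for line in range(1, 8):
            for gen in ("G1", "G2", "G3", "G4"):
                records.append(
                    {
                        "sample_id": f"{loc}_l{line}_{gen}",
                        "location": loc,
                        "generation": gen,
                        "mode": mode,
                        "line": str(line),
                    }
                )
    meta = pd.DataFrame(records).set_index("sample_id")

    counts = pd.DataFrame(
        0, index=pd.Index(taxa, name="taxon_id"), columns=meta.index, dtype=np.int64
    )
    z = _standardized(traits)
    host_mask = np.array([t not in symbiont_taxa for t in taxa])
    # a ubiquitous core community shared by every sample: whole-body
    # insect surveys share common taxa across hosts, and between-sample
    # normalisation is only defined when libraries overlap
    core_idx = rng.choice(np.flatnonzero(host_mask), size=n_core_taxa, replace=False)
    core_p = np.zeros(n_taxa)
    core_p[core_idx] = np.exp(rng.normal(0.0, 1.0, n_core_taxa))
    core_p /= core_p.sum()
    group_keys = sorted(STUDY_GROUP_REGIMES)
    for k, (mode, gen) in enumerate(group_keys):
        regime = STUDY_GROUP_REGIMES[(mode, gen)]
        samples = list(meta.index[(meta["mode"] == mode) & (meta["generation"] == gen)])
        overrides = dict(STUDY_PARAMS[regime])
        cfg = ScenarioConfig(
            regime=regime,
            n_taxa=n_taxa,
            n_samples=len(samples),
            read_depth_mean=depth_mean,
            read_depth_sigma=depth_sigma,
            seed=seed + 101 + k,
            **overrides,
        )
        grng = np.random.default_rng(cfg.seed)
        weights, _ = _regime_weights(regime, z, cfg, grng, len(samples))
        weights[~host_mask, :] = 0.0
        weights = weights / weights.sum(axis=0)
        weights = (1.0 - core_share) * weights + core_share * core_p[:, None]
        if mode == "asexual":
            weights *= 1.0 - endosymbiont_share
            weights[-2, :] = endosymbiont_share * 0.8
            weights[-1, :] = endosymbiont_share * 0.2
        depths = _sample_depths(cfg, grng, len(samples))
        counts.loc[:, samples] = _draw_counts(weights, depths, grng)

    contaminant_pool = [t for t in taxa[: n_taxa - 2] if t not in symbiont_taxa]
    picks = rng.choice(len(contaminant_pool), size=12, replace=False)
    kinds = (
        ["chloroplast"] * 4 + ["mitochondria"] * 3 + ["archaea"] * 3
        + ["unknown_phylum"] * 2
    )
    contaminants = {contaminant_pool[p]: kind for p, kind in zip(picks, kinds)}
    taxonomy = default_taxonomy(
        taxa, seed=seed + 7, symbiont_taxa=symbiont_taxa, contaminants=contaminants
    )
    truth = {
        "group_regimes": {
            f"{mode}:{gen}": regime
            for (mode, gen), regime in sorted(STUDY_GROUP_REGIMES.items())
        },
        "symbiont_taxa": list(symbiont_taxa),
        "contaminants": dict(sorted(contaminants.items())),
        "seed": seed,
        "n_taxa": n_taxa,
        "depth_mean": depth_mean,
        "depth_sigma": depth_sigma,
        "endosymbiont_share": endosymbiont_share,
    }
    table = CommunityTable(counts)
    return FixtureBundle(table, taxonomy, tree, SampleMetadata(meta), truth)
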