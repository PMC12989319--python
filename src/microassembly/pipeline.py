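"""Configured, logged, seed-pinned end-to-end runs.

A run reproduces the study's analysis graph on any input set:

* contaminant filtering → shallow-sample exclusion → rarefaction gives
  the *full* dataset track (alpha/beta diversity, ordination, PERMANOVA,
  assembly-process partition);
* removing the endosymbiont genus from the rarefied table gives the
  *reduced* track (TMM-normalised for diversity and ordination; integer
  counts feed the Raup–Crick null), analysed identically;
* the endosymbiont's own reads are extracted from the TMM-normalised
  un-rarefied table as a separate count track.

Every output file is listed in a manifest with a SHA-256 digest, so two
runs with the same configuration can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .assembly import (
    NullModelConfig,
    beta_nti,
    build_pair_table,
    raup_crick_bray,
    summarize_processes,
    SELECTION_CLASSES,
)
from .containers import CommunityTable
from .diversity import alpha_diversity, bray_curtis, pcoa, permanova_terms
from .preprocess import (
    DEFAULT_REMOVE_RULES,
    FilterSpec,
    drop_shallow_samples,
    extract_taxon_counts,
    filter_taxa,
    normalize,
    rarefy,
    taxa_matching,
    tmm_factors,
)

__version__ = "0.1.0"

log = logging.getLogger("microassembly")


@dataclass
class RunConfig:
    """All inputs, parameters and seeds of one pipeline run."""

    counts: str = ""
    taxonomy: str = ""
    metadata: str = ""
    tree: str = ""
    out_dir: str = "results"
    rarefaction_depth: int = 1196
    rarefaction_seed: int = 1
    remove_rules: list[tuple[str, str]] = field(
        default_factory=lambda: [list(r) for r in DEFAULT_REMOVE_RULES]
    )
    endosymbiont_rank: str = "genus"
    endosymbiont_label: str = "Wolbachia"
    n_null: int = 999
    null_seed: int = 1
    abundance_weighted: bool = True
    permanova_terms: list[str] = field(
        default_factory=lambda: ["mode", "generation", "location"]
    )
    n_permutations: int = 999
    permanova_seed: int = 1
    group_columns: list[str] = field(default_factory=lambda: ["mode", "generation"])

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a ``key = value`` config file (# starts a comment).

        List-valued keys take comma-separated entries; filter rules are
        written ``rank:label``.
        """
        cfg = cls()
        int_keys = {
            "rarefaction_depth", "rarefaction_seed", "n_null", "null_seed",
            "n_permutations", "permanova_seed",
        }
        list_keys = {"permanova_terms", "group_columns"}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if not hasattr(cfg, key):
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "remove_rules":
                    rules = []
                    for item in value.split(","):
                        rank, _, label = item.strip().partition(":")
                        rules.append([rank, label])
                    setattr(cfg, key, rules)
                elif key in list_keys:
                    setattr(cfg, key, [v.strip() for v in value.split(",")])
                elif key in int_keys:
                    setattr(cfg, key, int(value))
                elif key == "abundance_weighted":
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                else:
                    setattr(cfg, key, value)
        return cfg


@dataclass
class RunManifest:
    """Record of a completed run: config hash, output digests, warnings."""

    version: str
    config_hash: str
    config: dict
    files: dict[str, str] = field(default_factory=dict)
    warnings: list[dict] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    complete: bool = False

    def add_files(self, paths) -> None:
        for p in paths:
            p = Path(p)
            self.files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def warn(self, stage: str, kind: str, detail: str) -> None:
        self.warnings.append({"stage": stage, "kind": kind, "detail": detail})
        log.warning("%s: %s: %s", stage, kind, detail)

    def note(self, stage: str, detail: str) -> None:
        self.stages.append({"stage": stage, "detail": detail})
        log.info("%s: %s", stage, detail)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return manifest

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s: failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def _analyze_track(
    name: str,
    int_table: CommunityTable,
    diversity_table: CommunityTable,
    metadata,
    tree,
    config: RunConfig,
    manifest: RunManifest,
) -> dict[str, pd.DataFrame]:
    """Diversity + assembly results for one dataset track.

    ``int_table`` carries integer (rarefied) counts for the null models;
    ``diversity_table`` the abundances used for alpha/beta diversity
    (equal to ``int_table`` on the full track, TMM-normalised on the
    reduced track).
    """
    results: dict[str, pd.DataFrame] = {}
    alpha = alpha_diversity(diversity_table)
    results[f"alpha_{name}"] = alpha.reset_index()

    dm = bray_curtis(diversity_table)
    results[f"bray_curtis_{name}"] = mio.distance_matrix_to_long(dm)

    ordination = pcoa(dm)
    coords = ordination.coordinates.iloc[:, : min(4, ordination.coordinates.shape[1])]
    results[f"pcoa_{name}"] = coords.reset_index()
    results[f"pcoa_eigenvalues_{name}"] = pd.DataFrame(
        {
            "axis": np.arange(1, ordination.proportion_explained.size + 1),
            "eigenvalue": ordination.eigenvalues[
                : ordination.proportion_explained.size
            ],
            "proportion_explained": ordination.proportion_explained,
        }
    )

    meta_df = metadata.table
    results[f"permanova_{name}"] = permanova_terms(
        dm,
        meta_df,
        [t for t in config.permanova_terms if t in meta_df.columns],
        n_permutations=config.n_permutations,
        seed=config.permanova_seed,
    )

    null_cfg = NullModelConfig(
        n_null=config.n_null,
        seed=config.null_seed,
        abundance_weighted=config.abundance_weighted,
    )
    nti = beta_nti(int_table, tree, null_cfg)
    groups = metadata.group_key(int_table.sample_ids, config.group_columns)
    pairs = [
        (a, b)
        for i, a in enumerate(int_table.sample_ids)
        for b in int_table.sample_ids[i + 1 :]
        if groups[a] == groups[b]
    ]
    rc = raup_crick_bray(int_table, null_cfg, pairs=pairs)
    pair_table = build_pair_table(nti, rc, groups, within_groups_only=True)
    results[f"pairs_{name}"] = pair_table
    results[f"process_summary_{name}"] = summarize_processes(pair_table)
    manifest.note(
        f"assembly_{name}",
        f"{len(pair_table)} within-group pairs over "
        f"{int_table.n_samples} samples",
    )
    return results


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis graph and write all result TSVs.

    Deterministic and idempotent for a fixed configuration: rerunning
    produces byte-identical outputs.  Raises on any stage error, naming
    the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), config=config.to_dict()
    )
    try:
        with _stage(manifest, "read_inputs"):
            table = mio.read_community_table(config.counts)
            taxonomy = mio.read_taxonomy(config.taxonomy)
            metadata = mio.read_metadata(config.metadata)
            tree = mio.read_tree(config.tree)
            metadata.require_samples(table.sample_ids)
            manifest.note(
                "read_inputs",
                f"{table.n_taxa} taxa × {table.n_samples} samples",
            )

        with _stage(manifest, "filter_taxa"):
            spec = FilterSpec([tuple(r) for r in config.remove_rules])
            filtered, removed = filter_taxa(table, taxonomy, spec)
            manifest.note("filter_taxa", f"removed {len(removed)} contaminant taxa")

        with _stage(manifest, "endosymbiont_counts"):
            factors = tmm_factors(filtered)
            normalized_unrarefied = normalize(filtered, factors)
            symbiont = extract_taxon_counts(
                normalized_unrarefied,
                taxonomy,
                config.endosymbiont_rank,
                config.endosymbiont_label,
            )
            symbiont_table = symbiont.rename("reads").reset_index()

        with _stage(manifest, "drop_shallow"):
            deep, excluded = drop_shallow_samples(filtered, config.rarefaction_depth)
            for sample, depth in excluded:
                manifest.warn(
                    "drop_shallow", "excluded_sample", f"{sample} (depth {depth})"
                )

        with _stage(manifest, "rarefy"):
            full_table, dropped = rarefy(
                deep, config.rarefaction_depth, config.rarefaction_seed
            )
            manifest.note(
                "rarefy",
                f"depth {config.rarefaction_depth}, seed "
                f"{config.rarefaction_seed}; {len(dropped)} all-zero taxa dropped; "
                f"{full_table.n_taxa} taxa retained",
            )

        results: dict[str, pd.DataFrame] = {"wolbachia_counts": symbiont_table}
        with _stage(manifest, "full_track"):
            results.update(
                _analyze_track(
                    "full", full_table, full_table, metadata, tree, config, manifest
                )
            )

        with _stage(manifest, "reduced_track"):
            symbiont_ids = taxa_matching(
                full_table, taxonomy, config.endosymbiont_rank,
                config.endosymbiont_label,
            )
            reduced_counts = full_table.counts.drop(index=symbiont_ids)
            reduced = CommunityTable(reduced_counts)
            reduced, _ = reduced.drop_empty_taxa()
            empty_samples = [
                s for s, d in reduced.depths().items() if d == 0
            ]
            if empty_samples:
                for s in empty_samples:
                    manifest.warn(
                        "reduced_track", "empty_sample_after_removal", str(s)
                    )
                reduced = reduced.select_samples(
                    [s for s in reduced.sample_ids if s not in set(empty_samples)]
                )
            reduced_factors = tmm_factors(reduced)
            reduced_norm = normalize(reduced, reduced_factors)
            manifest.note(
                "reduced_track",
                f"removed {len(symbiont_ids)} endosymbiont taxa; "
                f"{reduced.n_taxa} taxa remain",
            )
            results.update(
                _analyze_track(
                    "reduced", reduced, reduced_norm, metadata, tree, config, manifest
                )
            )

        with _stage(manifest, "write_results"):
            provenance = pd.DataFrame(
                sorted(
                    (k, json.dumps(v) if isinstance(v, (list, dict)) else str(v))
                    for k, v in config.to_dict().items()
                ),
                columns=["key", "value"],
            )
            results["run_provenance"] = provenance
            written = mio.write_tidy_results(results, out_dir)
            manifest.add_files(written)

        manifest.complete = True
        manifest.write(out_dir / "manifest.json")
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()


def score_recovery(pair_table: pd.DataFrame, truth: dict) -> pd.DataFrame:
    """Score inferred assembly processes against generator ground truth.

    ``truth`` is a fixture truth record: either a single-scenario record
    with a ``regime`` key or a study record with ``group_regimes``
    (group key → regime).  For non-neutral regimes a group matches when
    its modal inferred class equals the generating regime; for neutral,
    when selection classes jointly hold ≤ 10% of pairs.
    """
    if "group_regimes" in truth:
        regime_of = dict(truth["group_regimes"])
    elif "regime" in truth:
        regime_of = None
    else:
        raise ValueError("truth record lacks 'regime' or 'group_regimes'")
    if pair_table.empty:
        raise ValueError("no classified pairs to score")
    rows = []
    for group, sub in pair_table.groupby("group", sort=True):
        if regime_of is None:
            regime = truth["regime"]
        elif group in regime_of:
            regime = regime_of[group]
        else:
            continue
        frac = sub["process"].value_counts(normalize=True)
        modal_class = frac.index[0]
        selection_frac = sum(frac.get(c, 0.0) for c in SELECTION_CLASSES)
        if regime == "neutral":
            matched = selection_frac <= 0.10
        else:
            matched = modal_class == regime
        rows.append(
            {
                "group": group,
                "true_regime": regime,
                "modal_class": modal_class,
                "modal_fraction": float(frac.iloc[0]),
                "selection_fraction": float(selection_frac),
                "n_pairs": int(len(sub)),
                "matched": bool(matched),
            }
        )
    return pd.DataFrame(rows)
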