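"""End-to-end pipeline driver: one JSON config in, one output directory out.

Runs the tutorial sequence — import (or simulate), normalize, set
targets, count, embed, project, cluster, stability, characterize,
compare, plot — writing every intermediate table, a run log with the
fully materialized configuration, and a JSON summary of the key
statistics.  A fixed seed makes reruns byte-identical for every
non-stochastic stage (and for the stochastic ones too, since all of them
accept the seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .clustering import cluster_stability, cluster_targets
from .compare import compare_embeddings, cross_targets, rsa_frame
from .embedding import embed_targets, project_study
from .errors import ConfigurationError
from .metrics import characterize_targets, count_targets, summarize_targets
from .preprocess import normalize
from .plots import plot_embedding_map, plot_wordclouds
from .study import AssociationStudy, import_study, save_study, set_targets
from .synthetic import GeneratorConfig, Topic, default_config, generate_study

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "input", "generator", "normalize", "targets", "count", "embedding",
    "projection", "clustering", "stability", "characterize", "summarize",
    "compare", "plots", "seed",
}


def _validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    if ("input" in config) == ("generator" in config):
        raise ConfigurationError(
            "config must have exactly one of 'input' (a CSV path) or "
            "'generator' (a simulation block)"
        )
    if "clustering" in config and "embedding" not in config:
        raise ConfigurationError(
            "clustering requested but no 'embedding' stage configured"
        )
    if "stability" in config and "clustering" not in config:
        raise ConfigurationError(
            "stability requested but no 'clustering' stage configured"
        )
    if "projection" in config and "embedding" not in config:
        raise ConfigurationError(
            "projection requested but no 'embedding' stage configured"
        )


def _generator_from_block(block: dict, seed: int) -> GeneratorConfig:
    if block.get("default", True):
        return default_config(
            n_participants=block.get("n_participants", 1000),
            n_topics=block.get("n_topics", 6),
            vocab_size=block.get("vocab_size", 60),
            seed=block.get("seed", seed),
        )
    topics = tuple(
        Topic(label=t["label"], vocabulary=tuple(t["vocabulary"]),
              weight=t.get("weight", 1.0))
        for t in block["topics"]
    )
    return GeneratorConfig(
        n_participants=block.get("n_participants", 1000),
        top_cue=block.get("top_cue", "intelligence"),
        topics=topics,
        group_vars={k: tuple(v) for k, v in block.get("group_vars", {}).items()},
        group_effects=block.get("group_effects", {}),
        n_first=block.get("n_first", 5),
        n_second=block.get("n_second", 5),
        zipf_exponent=block.get("zipf_exponent", 1.0),
        topic_fidelity=block.get("topic_fidelity", 0.8),
        typo_rate=block.get("typo_rate", 0.0),
        seed=block.get("seed", seed),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stages in order; returns the output directory."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text(encoding="utf-8"))
    _validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {}
    effective: dict[str, Any] = {"seed": seed, "version": __version__}

    # --- import or simulate
    if "generator" in config:
        gen = _generator_from_block(config["generator"], seed)
        study = generate_study(gen)
        effective["generator"] = {
            "n_participants": gen.n_participants,
            "n_topics": len(gen.topics),
            "n_first": gen.n_first,
            "n_second": gen.n_second,
            "seed": gen.seed,
        }
    else:
        block = config["input"]
        raw = pd.read_csv(block["path"], dtype=str, keep_default_na=False)
        study = import_study(
            raw,
            participant_col=block.get("participant_col", "participant_id"),
            cue_col=block.get("cue_col", "cue"),
            response_col=block.get("response_col", "response"),
            participant_vars=block.get("participant_vars", []),
            cue_vars=block.get("cue_vars", []),
            response_vars=block.get("response_vars", []),
        )
        effective["input"] = block
    summary["n_participants"] = int(study.participants["participant_id"].nunique())
    summary["n_response_tokens"] = int(len(study.responses))

    # --- normalize
    norm_block = config.get("normalize")
    if norm_block is not None:
        norm_block = dict(norm_block) if isinstance(norm_block, dict) else {}
        study = normalize(study, **norm_block)
        effective["normalize"] = study.meta["normalized"]

    # --- targets
    source = config.get("targets", {}).get("source", "cues")
    study = set_targets(study, source=source)
    effective["targets"] = {"source": source}
    count_block = config.get("count", {})
    study = count_targets(study, scope=count_block.get("scope", "first"))
    summary["n_targets"] = int(len(study.targets))

    # --- characterize / summarize
    if "characterize" in config:
        block = config["characterize"]
        study = characterize_targets(
            study,
            characteristics=block.get("characteristics"),
            lookup=block["lookup"],
        )
        effective["characterize"] = {"lookup": str(block["lookup"])}
    if "summarize" in config:
        block = config["summarize"]
        study = summarize_targets(
            study,
            response_var=block.get("response_var", "response_position"),
            fun=block.get("fun", "mean"),
        )
        effective["summarize"] = block

    # --- embed / project / cluster / stability
    if "embedding" in config:
        block = config["embedding"] or {}
        study = embed_targets(
            study,
            method=block.get("method", "ppmi-svd"),
            n_dim=block.get("n_dim"),
            seed=seed,
            smoothing=block.get("smoothing"),
        )
        effective["embedding"] = {
            "method": study.embedding.method,
            "n_dim": study.embedding.n_dim,
        }
        study.embedding.to_csv(
            out_dir / "embedding.csv", out_dir / "embedding_meta.json"
        )
    if "clustering" in config:
        block = config["clustering"] or {}
        study = cluster_targets(
            study,
            method=block.get("method", "louvain"),
            n_clusters=block.get("n_clusters"),
            resolution=block.get("resolution", 1.0),
            seed=seed,
        )
        effective["clustering"] = study.meta["clustering"]
        sizes = study.targets["cluster"].value_counts().sort_index()
        summary["cluster_sizes"] = {str(k): int(v) for k, v in sizes.items()}
    if "stability" in config:
        block = config["stability"] or {}
        stability = cluster_stability(
            study, n_bootstrap=block.get("n_bootstrap", 100), seed=seed
        )
        stability.pairwise.to_csv(out_dir / "stability_pairwise.csv")
        stability.cluster_level.to_csv(out_dir / "stability_cluster_level.csv")
        effective["stability"] = {"n_bootstrap": stability.n_bootstrap}
        diag = stability.cluster_level.to_numpy().diagonal()
        summary["stability_diagonal"] = [round(float(v), 4) for v in diag]
    if "projection" in config:
        block = config["projection"] or {}
        study = project_study(
            study,
            method=block.get("method", "umap"),
            n_dim=block.get("n_dim", 2),
            seed=seed,
        )
        effective["projection"] = {"method": block.get("method", "umap")}
        study.embedding.to_csv(
            out_dir / "projection.csv", out_dir / "projection_meta.json"
        )

    # --- comparisons
    if "compare" in config:
        block = config["compare"] or {}
        variables = block.get("participant_vars", [])
        if "cluster" in (study.targets.columns if study.targets is not None else []):
            for var in variables:
                table = cross_targets(study, var, "cluster", normalize=True)
                table.to_csv(out_dir / f"cross_{var}.csv")
        if block.get("rsa", True) and variables:
            results = compare_embeddings(
                study, variables, type=block.get("rsa_type", "lower_triangle")
            )
            frame = rsa_frame(results)
            frame.to_csv(out_dir / "rsa.csv", index=False)
            summary["rsa"] = {
                f"{r.variable}: {r.group_a} vs {r.group_b}": round(r.rho, 4)
                for r in results
            }
        effective["compare"] = block

    # --- plots
    if "plots" in config:
        block = config["plots"] or {}
        if study.embedding is not None and study.embedding.n_dim == 2:
            plot_embedding_map(
                study,
                out_dir / "embedding_map.svg",
                color_by="cluster" if "cluster" in study.targets.columns else None,
                min_frequency=block.get("min_frequency", 0),
            )
        if "cluster" in (study.targets.columns if study.targets is not None else []):
            plot_wordclouds(
                study, out_dir / "wordclouds.svg", facet_by="cluster", seed=seed
            )
        effective["plots"] = block

    save_study(study, out_dir / "study")
    (out_dir / "run_config.json").write_text(
        json.dumps(effective, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
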