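"""End-to-end workflow: validation, filtering, CST typing, differential
abundance, gestational-age trends and diversity, with a run manifest.

Stages run in the study's order; a stage failure halts the run with a
stage-named error, keeping the outputs already written.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    CountTable,
    SampleMetadata,
    prevalence_filter,
    read_count_table,
    read_metadata,
    to_relative_abundance,
    validate_metadata,
)
from .differential import results_to_frame, run_group_comparison
from .divergence import cst_frequencies, label_csts, pairwise_divergence, ward_cluster
from .diversity import compare_diversity
from .trends import run_trend_analysis, trend_results_to_frame

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All thresholds, model options and seeds for one pipeline run."""

    counts_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    min_prevalence: float = 0.25
    fdr: float = 0.1
    fc_threshold: float = 1.5
    n_clusters: int = 3
    cst_metric: str = "jsd"  # or "js_distance"
    quad_points: int = 25
    n_restarts: int = 3
    max_poly_degree: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cst_metric not in ("jsd", "js_distance"):
            raise ValueError("cst_metric must be 'jsd' or 'js_distance'")
        if not 1 <= self.max_poly_degree <= 7:
            raise ValueError("max_poly_degree must be in 1..7")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("counts_path", "metadata_path", "out_dir")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_all(
    config: RunConfig,
    table: CountTable | None = None,
    meta: list[SampleMetadata] | None = None,
) -> dict:
    """Execute every stage; returns a dict of stage results and output paths.

    Inputs may be passed in memory; otherwise they are read from the paths
    in ``config`` and cross-validated before any model is fitted.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.content_hash()}

    # ---- load & validate --------------------------------------------------
    try:
        if table is None:
            table = read_count_table(config.counts_path)
        if meta is None:
            meta = read_metadata(config.metadata_path, table=table)
        else:
            validate_metadata(table, meta)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # ---- prevalence filter ------------------------------------------------
    try:
        filtered = prevalence_filter(table, config.min_prevalence)
        if filtered.n_taxa == 0:
            raise ValueError("no taxa survive the prevalence filter")
        results["n_taxa_retained"] = filtered.n_taxa
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # ---- CST typing -------------------------------------------------------
    try:
        states = to_relative_abundance(table)  # full composition, all taxa
        dist = pairwise_divergence(states, metric=config.cst_metric)
        assign = ward_cluster(dist, n_clusters=config.n_clusters)
        assign = label_csts(assign, states, table.taxa)
        freqs = cst_frequencies(assign, meta)
        cst_df = assign.to_frame(meta)
        cst_df["config_hash"] = config.content_hash()
        cst_df.to_csv(out / "cst_assignments.tsv", sep="\t", index=False)
        freqs.to_csv(out / "cst_frequencies.tsv", sep="\t")
        results["cst_assignments"] = assign
        results["cst_frequencies"] = freqs
    except Exception as exc:
        raise PipelineError("cst", str(exc)) from exc

    # ---- differential abundance ------------------------------------------
    try:
        diff = run_group_comparison(
            filtered,
            meta,
            fdr_threshold=config.fdr,
            fc_threshold=config.fc_threshold,
            n_restarts=config.n_restarts,
            restart_seed=config.seed,
            quad_points=config.quad_points,
        )
        diff_df = results_to_frame(diff)
        diff_df["config_hash"] = config.content_hash()
        diff_df.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        results["differential_abundance"] = diff
        results["n_significant"] = int(sum(r.significant for r in diff))
    except Exception as exc:
        raise PipelineError("diffabund", str(exc)) from exc

    # ---- gestational-age trends (term group) ------------------------------
    try:
        intervals, trends = run_trend_analysis(
            filtered,
            meta,
            fdr_threshold=config.fdr,
            fc_threshold=config.fc_threshold,
            max_degree=config.max_poly_degree,
            n_restarts=config.n_restarts,
            restart_seed=config.seed,
            quad_points=config.quad_points,
        )
        trend_df = trend_results_to_frame(trends)
        trend_df["config_hash"] = config.content_hash()
        trend_df.to_csv(out / "gestational_trends.tsv", sep="\t", index=False)
        results["intervals"] = intervals
        results["trends"] = trends
    except Exception as exc:
        raise PipelineError("trends", str(exc)) from exc

    # ---- diversity ---------------------------------------------------------
    try:
        div = compare_diversity(states, meta)
        div.per_sample.to_csv(out / "shannon_diversity.tsv", sep="\t", index=False)
        with open(out / "diversity_comparison.json", "w") as fh:
            json.dump(
                {
                    "lme_estimate": div.lme_estimate,
                    "lme_se": div.lme_se,
                    "lme_p": div.lme_p,
                    "group_summary": div.group_summary.to_dict(orient="records"),
                    "config_hash": config.content_hash(),
                },
                fh,
                indent=1,
            )
        results["diversity"] = div
    except Exception as exc:
        raise PipelineError("diversity", str(exc)) from exc

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "n_taxa_retained": filtered.n_taxa,
        "n_significant_group": results["n_significant"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
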