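"""End-to-end driver: read -> filter -> align -> standardize -> (tune | fit)
-> aggregate -> cluster -> survival evaluation -> enrichment, with every
intermediate artifact written to a run directory."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cca import SCCAConfig, aggregate_scores, fit_scca
from .cluster import kmeans_cluster, select_k
from .enrichment import ora_test, rank_genes_by_avg_abs_weight, subtype_de
from .io import (
    GeneSetDB,
    align_samples,
    filter_missing_features,
    read_gmt,
    read_omics_matrix,
    read_survival,
    standardize_columns,
)
from .survival import cox_fit_subtypes

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_frames"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (file inputs + all stage options)."""

    x_path: str
    y_path: str
    survival_path: str
    gmt_path: str | None = None
    scca: SCCAConfig = field(default_factory=SCCAConfig)
    k: int | None = 3
    k_range: list[int] | None = None
    aggregation: str = "both_views"
    sep_convention: str = "reciprocal"
    max_missing_rate: float = 0.05
    alpha: float = 0.05
    out_dir: str = "scclust_run"
    seed: int = 0
    n_restarts: int = 25

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load configuration from TOML or YAML."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            import tomllib

            raw = tomllib.loads(text)
        scca = SCCAConfig(**raw.pop("scca", {}))
        return cls(scca=scca, **raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline from files; returns the run directory."""
    for name in ("x_path", "y_path", "survival_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p!r} does not exist")
    x = read_omics_matrix(config.x_path)
    y = read_omics_matrix(config.y_path)
    surv = read_survival(config.survival_path)
    db = read_gmt(config.gmt_path) if config.gmt_path else None
    return run_pipeline_frames(x, y, surv, db, config)


def run_pipeline_frames(
    x: pd.DataFrame,
    y: pd.DataFrame,
    surv: pd.DataFrame,
    db: GeneSetDB | None,
    config: PipelineConfig,
) -> Path:
    """Run the pipeline on in-memory inputs (used by the CLI and tests)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"scclust {__version__}", f"seed {config.seed}"]

    x, dropped_x = filter_missing_features(x, config.max_missing_rate)
    y, dropped_y = filter_missing_features(y, config.max_missing_rate)
    log_lines.append(f"missing-filter dropped: x={len(dropped_x)} y={len(dropped_y)}")
    x, y, surv = align_samples(x, y, surv)
    expr_raw = x.copy()  # unstandardized expression for DE
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xs = standardize_columns(x)
        ys = standardize_columns(y)
    log_lines.append(f"aligned samples: {len(xs)}")

    cfg = config.scca
    result = fit_scca(xs, ys, cfg)
    result.weight_frame("x").to_csv(out / "weights_x.tsv", sep="\t")
    result.weight_frame("y").to_csv(out / "weights_y.tsv", sep="\t")
    scores = aggregate_scores(result, mode=config.aggregation, sample_ids=xs.index)
    scores.to_csv(out / "scores.tsv", sep="\t")
    log_lines.append(
        "canonical correlations: "
        + ", ".join(f"{c:.4f}" for c in result.correlations)
    )

    if config.k is None:
        k, diag = select_k(
            scores.to_numpy(),
            config.k_range or range(2, 7),
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        diag.to_csv(out / "cluster_diagnostics.tsv", sep="\t", index=False)
    else:
        k = config.k
    assignment = kmeans_cluster(
        scores, k, seed=config.seed, n_restarts=config.n_restarts
    )
    assignment.to_frame().to_csv(out / "subtypes.tsv", sep="\t")

    fit = cox_fit_subtypes(
        surv["time"].to_numpy(), surv["event"].to_numpy(), assignment.labels
    )
    summary = fit.summary(config.sep_convention)
    summary.update(
        k=k,
        n_samples=len(xs),
        n_components=cfg.n_components,
        tau1=cfg.tau1,
        tau2=cfg.tau2,
        aggregation=config.aggregation,
        seed=config.seed,
        correlations=[round(float(c), 6) for c in result.correlations],
    )

    if db is not None:
        db_m = db.restrict(list(expr_raw.columns))
        top_hits = {}
        for subtype in sorted(np.unique(assignment.labels)):
            de = subtype_de(expr_raw, assignment.labels, subtype, alpha=config.alpha)
            de.to_csv(out / f"de_subtype{subtype}.tsv", sep="\t")
            for direction in ("up", "down"):
                genes = list(de.index[de["direction"] == direction])
                if not genes:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        ora = ora_test(genes, db_m)
                    except ValueError:
                        continue
                ora.to_csv(out / f"ora_subtype{subtype}_{direction}.tsv", sep="\t")
                hit = ora.iloc[0]
                top_hits[f"subtype{subtype}_{direction}"] = {
                    "set": str(ora.index[0]),
                    "q_value": round(float(hit["q_value"]), 8),
                }
        summary["top_enriched"] = top_hits
        ranking = rank_genes_by_avg_abs_weight(result, "x")
        ranking.rename("avg_abs_weight").to_csv(out / "gene_ranking.tsv", sep="\t")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
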