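"""End-to-end orchestration: simulate -> normalize -> screen -> train ->
evaluate -> enrich, with every artifact written to an output directory.

All randomness flows from a single run seed; per-stage sub-seeds are
derived by stable hashing (CRC-32) of the stage name, so re-running with
the same config and seed reproduces byte-identical statistical outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import io as eio
from .ensemble import FitConfig, cv_attribute_selection, risk_scores
from .evaluation import (auroc_confint, confusion_at_threshold, roc_points,
                         stage_holdout_protocol)
from .enrichment import enrich_pathways, top_overlap_pathways, DEFAULT_FDR
from .matrix import to_design
from .preprocess import preprocess, DEFAULT_TARGET_MEDIAN
from .screening import (screen_cohort, significance_counts, volcano_filter,
                        prevalence_summary, DEFAULT_ABS_LFC_MIN,
                        DEFAULT_NEGLOG10P_MIN, DEFAULT_P_THRESHOLDS)
from .synthetic import (CohortSpec, generate_cohort, generate_pathway_db,
                        ground_truth_to_dict)

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    out_dir: str = "results/pipeline"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    target_median: float = DEFAULT_TARGET_MEDIAN
    log2_floor: float = 1.0
    neglog10p_min: float = DEFAULT_NEGLOG10P_MIN
    abs_lfc_min: float = DEFAULT_ABS_LFC_MIN
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS
    n_pathways: int = 338
    n_background_genes: int = 8430
    planted_enriched: int = 10
    fdr: float = DEFAULT_FDR
    fisher_sided: str = "greater"
    score_mode: str = "oof"              # or "deployed"
    noncancer_test_fraction: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**doc.pop("cohort", {}))
        fit = FitConfig(**doc.pop("fit", {}))
        return cls(cohort=cohort, fit=fit, **doc)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write every artifact, return a summary dict.

    Artifacts under ``config.out_dir``: intensity.tsv, metadata.tsv,
    ground_truth.json, pathways.gmt, target_map.tsv, normalized.tsv,
    species_stats.tsv, featured_species.tsv, model.json,
    selected_species.tsv, roc.tsv, metrics.json, enrichment_<group>.tsv,
    top_pathways.tsv, summary.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    spec = replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
    cohort = generate_cohort(spec)
    eio.write_intensity_tsv(cohort.matrix, out / "intensity.tsv")
    eio.write_metadata_tsv(cohort.labels, out / "metadata.tsv")
    eio.write_json(ground_truth_to_dict(cohort.truth), out / "ground_truth.json")
    db, tmap, pw_truth = generate_pathway_db(
        n_pathways=config.n_pathways,
        n_background_genes=config.n_background_genes,
        planted_enriched=config.planted_enriched,
        seed=stage_seed(config.seed, "pathways"),
        mirna_ids=list(cohort.matrix.probe_ids),
        signal_mirna_ids=cohort.truth.planted_ids,
    )
    eio.write_gmt(db.pathways, out / "pathways.gmt")
    eio.write_target_map(tmap, out / "target_map.tsv")
    log.info("simulated cohort %dx%d, %d planted species",
             cohort.matrix.n_probes, cohort.matrix.n_samples,
             len(cohort.truth.planted_ids))

    # -- normalize ---------------------------------------------------------
    normalized, log2m = preprocess(cohort.matrix, background=0.0,
                                   target_median=config.target_median,
                                   floor=config.log2_floor)
    eio.write_intensity_tsv(normalized, out / "normalized.tsv")

    # -- screen ------------------------------------------------------------
    stats = screen_cohort(normalized, cohort.labels,
                          floor=config.log2_floor,
                          neglog10p_min=config.neglog10p_min,
                          abs_lfc_min=config.abs_lfc_min)
    featured = volcano_filter(stats, config.neglog10p_min, config.abs_lfc_min)
    counts = significance_counts(stats, config.p_thresholds)
    prev = prevalence_summary(cohort.matrix)
    eio.write_stats_tsv(stats, out / "species_stats.tsv", "probe_id")
    eio.write_stats_tsv(featured, out / "featured_species.tsv", "probe_id")

    # -- train -------------------------------------------------------------
    X, y, probe_ids, sample_ids = to_design(log2m, cohort.labels)
    fit_cfg = replace(config.fit, seed=stage_seed(config.seed, "train"))
    model = cv_attribute_selection(X, y, probe_ids, fit_cfg)
    eio.write_model_json(model, out / "model.json")
    sel = stats.loc[model.selected_ids].copy()
    sel["beta"] = [model.beta[i] for i in sel.index]
    eio.write_stats_tsv(sel, out / "selected_species.tsv", "probe_id")

    # -- evaluate ----------------------------------------------------------
    scores = (model.trace.oof_scores if config.score_mode == "oof"
              else risk_scores(model, X, probe_ids))
    roc = roc_points(scores, y)
    ci = auroc_confint(scores, y, method="delong")
    conf = confusion_at_threshold(scores, y)
    holdout = stage_holdout_protocol(
        log2m, cohort.labels, fit_cfg,
        noncancer_test_fraction=config.noncancer_test_fraction,
        seed=stage_seed(config.seed, "holdout"))
    import pandas as pd
    eio.write_stats_tsv(
        pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}),
        out / "roc.tsv", "point")
    metrics = {
        "score_mode": config.score_mode,
        "auroc": roc.auroc,
        "auroc_ci": list(ci),
        "accuracy": conf.accuracy,
        "sensitivity": conf.sensitivity,
        "specificity": conf.specificity,
        "n_selected": len(model.beta),
        "stage_holdout": {
            "auroc": holdout.roc.auroc,
            "auroc_ci": list(holdout.roc.ci),
            "accuracy": holdout.confusion.accuracy,
            "sensitivity": holdout.confusion.sensitivity,
            "specificity": holdout.confusion.specificity,
            "n_train_cancer": holdout.n_train_cancer,
            "n_train_noncancer": holdout.n_train_noncancer,
            "n_test_cancer": holdout.n_test_cancer,
            "n_test_noncancer": holdout.n_test_noncancer,
            "n_selected": len(holdout.model.beta),
        },
    }
    eio.write_json(metrics, out / "metrics.json")

    # -- enrich ------------------------------------------------------------
    groups = {
        "up": list(featured.index[featured["direction"] == "up"]),
        "down": list(featured.index[featured["direction"] == "down"]),
        "ns": [pid for pid in stats.index if pid not in set(featured.index)],
    }
    tables = {}
    for gname, mirnas in groups.items():
        genes = tmap.union_targets(mirnas)
        tables[gname] = enrich_pathways(genes, db, fdr=config.fdr,
                                        sided=config.fisher_sided)
        eio.write_stats_tsv(tables[gname], out / f"enrichment_{gname}.tsv",
                            "pathway_id")
    top = top_overlap_pathways(tables, k=10)
    eio.write_stats_tsv(top, out / "top_pathways.tsv", "pathway_id")

    summary = {
        "seed": config.seed,
        "thresholds": {
            "lambda": config.fit.lam, "n_folds": config.fit.n_folds,
            "coef_threshold": config.fit.coef_threshold,
            "neglog10p_min": config.neglog10p_min,
            "abs_lfc_min": config.abs_lfc_min,
            "fdr": config.fdr, "target_median": config.target_median,
        },
        "cohort": {"n_probes": cohort.matrix.n_probes,
                   "n_samples": cohort.matrix.n_samples,
                   "n_detected_any": prev.n_detected_any,
                   "n_detected_all": prev.n_detected_all,
                   "median_detected_per_subject":
                       float(prev.per_subject_counts.median())},
        "screening": {"significance_counts":
                      {str(k): v for k, v in counts.items()},
                      "n_featured": int(len(featured)),
                      "n_featured_up": int((featured["direction"] == "up").sum()),
                      "n_featured_down": int((featured["direction"] == "down").sum())},
        "model": {"n_selected": len(model.beta), "alpha": model.alpha},
        "evaluation": metrics,
        "enrichment": {g: int(tables[g]["significant"].sum()) for g in tables},
        "planted": {"n_planted": len(cohort.truth.planted_ids),
                    "planted_pathways": pw_truth.planted_pathway_ids},
    }
    eio.write_json(summary, out / "summary.json")
    return summary
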