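"""Stage orchestration: simulate -> extract -> classify -> report.

Each stage is a plain function over a :class:`~leafcode.config.RunConfig`
so it can be driven from the CLI, a notebook or the test suite alike.
Outputs land in a fixed tree under ``config.out_dir``::

    data/       rendered PNGs + manifest.csv (simulated runs)
    features/   features_adaxial.csv, features_abaxial.csv, sidecar JSON
    results/    <surface>/<classifier>/ CV outputs + summary table
    report/     ANOVA/Tukey/CI tables, heatmap and network files

Every stage writes ``run_metadata.json`` entries with the config hash
and seeds; no stage silently drops data — per-image failures are
collected and reported, and more than 5% failures aborts extraction.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio, synth
from .config import RunConfig
from .cv import (
    ClassifierSpec,
    CVResult,
    build_feature_table,
    cross_validate,
    make_folds,
)
from .network import build_similarity_network, render_outputs
from .stats import (
    ConfusionMatrix,
    anova_oneway,
    t_confidence_interval,
    tukey_hsd,
)
from .texture import EXTRACTOR_PARAMS, FEATURE_NAMES, assemble_feature_vector

logger = logging.getLogger("leafcode")


class StageError(RuntimeError):
    """A pipeline stage failed in a way that invalidates the run."""


def _record_metadata(config: RunConfig, stage: str, extra: dict | None = None) -> None:
    path = config.out_dir / "run_metadata.json"
    meta = {}
    if path.exists():
        meta = json.loads(path.read_text())
    meta.setdefault("config_hash", config.config_hash)
    meta.setdefault("seeds", config.to_dict()["seeds"])
    meta[stage] = {"completed": True, **(extra or {})}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))


def stage_simulate(config: RunConfig, force: bool = False) -> Path:
    """Generate the synthetic dataset (no-op when it already exists
    unless ``force``)."""
    data_dir = config.out_dir / "data"
    manifest = data_dir / "manifest.csv"
    if manifest.exists() and not force:
        logger.info("simulate: %s exists, skipping (use force to redo)", manifest)
        return manifest
    t0 = time.time()
    manifest = synth.generate_dataset(
        configs=None,
        out_dir=data_dir,
        seed=config.seeds.data,
        damage_rate_override=config.damage_rate,
    )
    _record_metadata(config, "simulate", {"seconds": round(time.time() - t0, 1)})
    logger.info("simulate: wrote %s in %.1fs", manifest, time.time() - t0)
    return manifest


def extract_features(
    entries: list[imgio.LeafManifestEntry],
    size: int = 512,
    include_damaged: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Run the full descriptor pipeline over manifest entries.

    Returns the feature table (one row per processed image) and a list
    of (image_path, error) pairs for images that failed any stage.
    Non-intact entries are skipped unless ``include_damaged``.
    """
    rows, failures = [], []
    for i, entry in enumerate(entries):
        if not entry.intact and not include_damaged:
            continue
        try:
            img = imgio.load_image(entry.image_path)
            mask = imgio.segment_leaf(img)
            img_s, mask_s = imgio.standardize(img, mask, size=size)
            rows.append(assemble_feature_vector(entry, img_s, mask_s))
        except Exception as exc:  # noqa: BLE001 - collected, reported
            failures.append((str(entry.image_path), str(exc)))
            logger.warning("extract: %s failed: %s", entry.image_path, exc)
        if (i + 1) % 100 == 0:
            logger.info("extract: %d/%d images", i + 1, len(entries))
    return pd.DataFrame(rows), failures


def stage_extract(config: RunConfig, force: bool = False) -> dict[str, Path]:
    """Extract per-surface feature CSVs plus the parameter sidecar."""
    manifest = config.manifest or (config.out_dir / "data" / "manifest.csv")
    if not manifest.exists():
        raise StageError(f"manifest not found: {manifest}")
    feat_dir = config.out_dir / "features"
    out = {s: feat_dir / f"features_{s}.csv" for s in ("adaxial", "abaxial")}
    if all(p.exists() for p in out.values()) and not force:
        logger.info("extract: feature CSVs exist, skipping")
        return out
    t0 = time.time()
    entries = imgio.read_manifest(manifest)
    table, failures = extract_features(
        entries, size=config.standard_size, include_damaged=config.include_damaged
    )
    n_attempted = len(table) + len(failures)
    if failures and len(failures) > 0.05 * n_attempted:
        raise StageError(
            f"{len(failures)}/{n_attempted} images failed extraction: "
            f"{failures[:5]}..."
        )
    feat_dir.mkdir(parents=True, exist_ok=True)
    for surface, path in out.items():
        sub = table[table["surface"] == surface]
        sub.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "params": EXTRACTOR_PARAMS,
        "standard_size": config.standard_size,
        "n_features": len(FEATURE_NAMES),
        "failures": failures,
        "config_hash": config.config_hash,
    }
    (feat_dir / "extractor_params.json").write_text(json.dumps(sidecar, indent=2))
    _record_metadata(
        config, "extract",
        {"seconds": round(time.time() - t0, 1), "n_failures": len(failures)},
    )
    logger.info("extract: %d rows in %.1fs", len(table), time.time() - t0)
    return out


def load_features(config: RunConfig) -> pd.DataFrame:
    feat_dir = config.out_dir / "features"
    frames = []
    for surface in ("adaxial", "abaxial"):
        path = feat_dir / f"features_{surface}.csv"
        if path.exists():
            frames.append(pd.read_csv(path, dtype={"leaf_id": str, "plant_id": str}))
    if not frames:
        raise StageError(f"no feature CSVs under {feat_dir}")
    return pd.concat(frames, ignore_index=True)


def _cv_result_to_json(result: CVResult) -> dict:
    return {
        "classifier": result.classifier,
        "surface_mode": result.surface_mode,
        "pooled_accuracy": result.pooled_accuracy,
        "fold_metrics": result.fold_metrics.round(12).to_dict(orient="records"),
        "per_class_f_pooled": {
            c: float(f)
            for c, f in zip(
                result.confusion.index,
                _pooled_class_f(result.confusion),
            )
        },
    }


def _pooled_class_f(confusion: pd.DataFrame) -> np.ndarray:
    from .stats import per_class_metrics

    cm = ConfusionMatrix.from_frame(confusion)
    return per_class_metrics(cm)["f"].to_numpy()


def run_cv(
    config: RunConfig, features: pd.DataFrame, mode: str, clf: str
) -> CVResult:
    table = build_feature_table(features, mode)
    folds = make_folds(
        table, k=config.k_folds, seed=config.seeds.folds,
        group_aware=config.group_aware,
    )
    spec = ClassifierSpec(name=clf, seed=config.seeds.classifiers)
    return cross_validate(table, spec, folds)


def stage_classify(config: RunConfig) -> pd.DataFrame:
    """Evaluate every classifier on every requested surface mode.

    Writes per-run metrics JSON, per-instance predictions and pooled
    confusion counts, plus a classifiers x surfaces summary table of
    pooled accuracy percentages.
    """
    features = load_features(config)
    res_dir = config.out_dir / "results"
    summary = pd.DataFrame(
        index=list(config.classifiers), columns=list(config.surfaces), dtype=float
    )
    t0 = time.time()
    for surface, mode in zip(config.surfaces, config.surface_modes()):
        for clf in config.classifiers:
            result = run_cv(config, features, mode, clf)
            out = res_dir / surface / clf
            out.mkdir(parents=True, exist_ok=True)
            (out / "metrics.json").write_text(
                json.dumps(_cv_result_to_json(result), indent=2, sort_keys=True)
            )
            result.predictions.to_csv(out / "predictions.csv", index=False,
                                      float_format="%.12g")
            result.confusion.to_csv(out / "confusion_counts.csv")
            result.fold_metrics.to_csv(out / "fold_metrics.csv", index=False,
                                       float_format="%.12g")
            summary.loc[clf, surface] = 100.0 * result.pooled_accuracy
            logger.info(
                "classify: %s / %s accuracy %.1f%%",
                surface, clf, 100.0 * result.pooled_accuracy,
            )
    res_dir.mkdir(parents=True, exist_ok=True)
    summary.round(4).to_csv(res_dir / "accuracy_table.csv")
    _record_metadata(config, "classify", {"seconds": round(time.time() - t0, 1)})
    return summary


def _load_fold_f(config: RunConfig, surface: str, clf: str) -> np.ndarray:
    path = config.out_dir / "results" / surface / clf / "fold_metrics.csv"
    return pd.read_csv(path)["weighted_f"].to_numpy()


def stage_report(config: RunConfig) -> dict:
    """Statistics and figures over the classify stage.

    Emits per-surface ANOVAs across algorithms, a cross-surface ANOVA
    on per-fold F-measures pooled over algorithms, Tukey tables, a
    t-based 95% CI table, and the confusion heatmap plus similarity
    network for the best classifier by pooled combined-surface
    accuracy (alphabetical on ties).
    """
    rep_dir = config.out_dir / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"anova": {}, "tukey": {}, "ci": []}

    if len(config.classifiers) >= 2:
        for surface in config.surfaces:
            groups = {c: _load_fold_f(config, surface, c) for c in config.classifiers}
            res = anova_oneway(list(groups.values()))
            report["anova"][surface] = res.__dict__
            tukey_hsd(groups).to_csv(
                rep_dir / f"tukey_{surface}.csv", index=False, float_format="%.6g"
            )
    else:
        logger.warning("report: fewer than 2 classifiers; per-surface ANOVA skipped")

    if len(config.surfaces) >= 2:
        by_surface = {
            s: np.concatenate(
                [_load_fold_f(config, s, c) for c in config.classifiers]
            )
            for s in config.surfaces
        }
        res = anova_oneway(list(by_surface.values()))
        report["anova"]["cross_surface"] = res.__dict__
        tukey_hsd(by_surface).to_csv(
            rep_dir / "tukey_cross_surface.csv", index=False, float_format="%.6g"
        )
    else:
        logger.warning("report: single surface mode; cross-surface ANOVA skipped")

    for surface in config.surfaces:
        for clf in config.classifiers:
            vals = _load_fold_f(config, surface, clf)
            mean, lo, hi = t_confidence_interval(vals)
            report["ci"].append(
                {"surface": surface, "classifier": clf,
                 "mean_f": mean, "ci_low": lo, "ci_high": hi}
            )
    pd.DataFrame(report["ci"]).to_csv(
        rep_dir / "f_measure_ci.csv", index=False, float_format="%.6g"
    )

    # best classifier on the last-listed (preferably combined) surface
    summary = pd.read_csv(
        config.out_dir / "results" / "accuracy_table.csv", index_col=0
    )
    pick_surface = "combined" if "combined" in summary.columns else summary.columns[-1]
    col = summary[pick_surface]
    best = sorted(col.index[col == col.max()])[0]
    report["best_classifier"] = best
    report["best_surface"] = pick_surface
    cm_df = pd.read_csv(
        config.out_dir / "results" / pick_surface / best / "confusion_counts.csv",
        index_col=0,
    )
    cm = ConfusionMatrix.from_frame(cm_df)
    graph = build_similarity_network(cm)
    render_outputs(cm, graph, rep_dir, layout_seed=config.seeds.layout, prefix=best)

    (rep_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _record_metadata(config, "report", {"best_classifier": best})
    return report


def run_all(config: RunConfig, force: bool = False) -> dict:
    """simulate (if configured) -> extract -> classify -> report."""
    stage = "simulate"
    try:
        if config.simulate and config.manifest is None:
            stage_simulate(config, force=force)
        stage = "extract"
        stage_extract(config, force=force)
        stage = "classify"
        stage_classify(config)
        stage = "report"
        return stage_report(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
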