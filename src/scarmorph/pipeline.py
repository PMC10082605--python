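"""End-to-end pipeline driver: simulate/load -> features -> MRMR -> classify.

The pipeline is a chain of file-level stages (simulate, extract, rank,
evaluate) so that a one-shot run and a staged run are literally the same
code path and therefore byte-identical given the same master seed.  Every
run leaves a ``run_meta.json`` with the resolved configuration and derived
seeds, sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, features, images, mrmr, simulate
from .errors import ParameterError

log = logging.getLogger("scarmorph")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[scarmorph] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "simulate"                 # "simulate" | "manifest"
    manifest: str | None = None
    design: simulate.CohortDesign = field(default_factory=simulate.CohortDesign)
    features: features.FeatureConfig = field(default_factory=features.FeatureConfig)
    mrmr_bins: int = mrmr.DEFAULT_BINS
    sgd: classify.SGDConfig = field(default_factory=classify.SGDConfig)
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "manifest"):
            raise ParameterError(f"mode must be simulate or manifest, got {self.mode!r}")
        if self.mode == "manifest" and not self.manifest:
            raise ParameterError("manifest mode requires a manifest path")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")

    def with_seed(self, seed: int) -> "PipelineConfig":
        design = dataclasses.replace(self.design, master_seed=seed)
        return dataclasses.replace(self, seed=seed, design=design)


def _dataclass_from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    if "design" in data:
        ddata = dict(data.pop("design"))
        if "class_params" in ddata:
            presets = {
                label: {ch: simulate.FiberClassParams(class_label=label, **pp)
                        for ch, pp in per_class.items()}
                for label, per_class in ddata.pop("class_params").items()}
            ddata["class_params"] = presets
        kwargs["design"] = _dataclass_from_dict(simulate.CohortDesign, ddata)
    if "features" in data:
        kwargs["features"] = _dataclass_from_dict(
            features.FeatureConfig, data.pop("features"))
    if "sgd" in data:
        kwargs["sgd"] = _dataclass_from_dict(classify.SGDConfig, data.pop("sgd"))
    kwargs.update(data)
    return _dataclass_from_dict(PipelineConfig, kwargs)


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_to_dict(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=str))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(design: simulate.CohortDesign, outdir: Path) -> Path:
    """Generate a cohort and write it (TIFFs + manifest); returns manifest path."""
    t0 = time.perf_counter()
    cohort = simulate.generate_cohort(design)
    manifest = images.write_cohort(cohort, Path(outdir) / "cohort")
    log.info("simulate: %d samples -> %s (%.1fs)",
             len(cohort), manifest, time.perf_counter() - t0)
    return manifest


def stage_extract(manifest: Path, fconfig: features.FeatureConfig,
                  out_csv: Path) -> Path:
    """Extract and aggregate the 28-feature table from a cohort on disk."""
    t0 = time.perf_counter()
    cohort = images.load_cohort(manifest)
    table = features.build_cohort_table(cohort, fconfig)
    features.write_feature_table(table, out_csv)
    log.info("extract: %d samples x %d features -> %s (%.1fs)",
             len(table), len(features.FEATURE_NAMES), out_csv,
             time.perf_counter() - t0)
    return Path(out_csv)


def stage_rank(features_csv: Path, bins: int, out_csv: Path) -> Path:
    """MRMR-rank the feature table; writes the rank/feature/criterion CSV."""
    table = features.read_feature_table(features_csv)
    ranking = mrmr.mrmr_rank(mrmr.discretize(table, bins=bins))
    mrmr.write_ranking(ranking, out_csv)
    log.info("rank: top feature %s -> %s", ranking.ranked_features[0], out_csv)
    return Path(out_csv)


def stage_evaluate(features_csv: Path, ranking_csv: Path,
                   config: PipelineConfig, outdir: Path) -> dict:
    """Subset sweep + final LOO model at best_n + one-vs-rest ROC/AUC."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    table = features.read_feature_table(features_csv)
    ranking = mrmr.read_ranking(ranking_csv)
    subsets = mrmr.incremental_subsets(ranking)

    evaluations, best_n = classify.subset_sweep(
        table, subsets, config.sgd, repeats=config.repeats,
        base_seed=config.seed)
    sweep = classify.evaluations_to_frame(evaluations)
    sweep.to_csv(outdir / "sweep.csv", index=False, float_format="%.12g")

    final_seed = int(np.random.SeedSequence([config.seed, 999])
                     .generate_state(1)[0] >> 1)
    accuracy, scores = classify.loo_evaluate(
        table, ranking.ranked_features[:best_n], config.sgd, seed=final_seed)
    rocs = classify.roc_auc(scores)
    for cls, r in rocs.items():
        pd.DataFrame({"fpr": r["fpr"], "tpr": r["tpr"],
                      "threshold": r["thresholds"]}).to_csv(
            outdir / f"roc_{cls}.csv", index=False, float_format="%.12g")
    matrix, class_order = classify.confusion(scores)

    report = {
        "n_samples": int(len(table)),
        "n_features": int(len(features.FEATURE_NAMES)),
        "best_n": int(best_n),
        "mean_accuracy_by_n": {int(e.subset_size): e.mean_accuracy
                               for e in evaluations},
        "best_mean_accuracy": max(e.mean_accuracy for e in evaluations),
        "loo_accuracy_best_subset": accuracy,
        "auc": {cls: r["auc"] for cls, r in rocs.items()},
        "confusion_matrix": {"classes": class_order,
                             "rows_true": matrix.tolist()},
        "note": ("group-difference p-values are reported without "
                 "multiple-testing correction"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("evaluate: best_n=%d loo_acc=%.3f (%.1fs)",
             best_n, accuracy, time.perf_counter() - t0)
    return report


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """One-shot pipeline: simulate/load -> extract -> rank -> evaluate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config_to_dict(config), "stages": {}}
    if config.mode == "simulate":
        manifest = stage_simulate(config.design, outdir)
    else:
        manifest = Path(config.manifest)
        if not manifest.exists():
            raise ParameterError(f"manifest not found: {manifest}")
    meta["stages"]["manifest"] = str(manifest)
    features_csv = stage_extract(manifest, config.features,
                                 outdir / "features.csv")
    ranking_csv = stage_rank(features_csv, config.mrmr_bins,
                             outdir / "ranking.csv")
    report = stage_evaluate(features_csv, ranking_csv, config, outdir)
    meta["stages"]["features"] = str(features_csv)
    meta["stages"]["ranking"] = str(ranking_csv)
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return report
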