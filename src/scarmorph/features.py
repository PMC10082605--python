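"""Per-sample 28-feature vectors and group-difference statistics.

Each imaged region yields 14 features per channel — 4 morphological
(density, length, width, alignment), 6 histogram and 4 GLCM statistics —
prefixed ``C-`` for the collagen (SHG) channel and ``E-`` for the elastin
(TPEF) channel.  A sample's 2-3 regions are averaged feature-wise into one
28-entry vector.  The canonical column order is all collagen features then
all elastin features, morphology -> histogram -> GLCM within each channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .images import CLASS_LABELS, Cohort, RegionRecord, denoise
from .morphology import morphology_features
from .texture import glcm, glcm_features, histogram_features

MORPHOLOGY_NAMES = ("density", "length", "width", "alignment")
HISTOGRAM_NAMES = ("mean_int", "std", "smoothness", "skewness",
                   "uniformity", "entropy")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")
PER_CHANNEL_NAMES = MORPHOLOGY_NAMES + HISTOGRAM_NAMES + GLCM_NAMES
CHANNEL_PREFIXES = {"collagen": "C", "elastin": "E"}

LABEL_COLUMN = "class_label"


def feature_names() -> list[str]:
    """The canonical 28 feature names, C-density ... E-homogeneity."""
    return [f"{CHANNEL_PREFIXES[ch]}-{name}"
            for ch in ("collagen", "elastin")
            for name in PER_CHANNEL_NAMES]


FEATURE_NAMES = feature_names()


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the extraction stages (denoise window, band-pass, GLCM)."""

    denoise_window: int | None = 3
    glcm_levels: int = 8
    glcm_distance: int = 1
    fft_r_min: float = 4.0
    fft_r_max_frac: float = 0.8
    fft_window: str = "hann"
    trace_min_length_px: float = 10.0


def extract_region_features(region: RegionRecord,
                            config: FeatureConfig | None = None) -> dict[str, float]:
    """Run denoise -> morphology + texture on both channels of one region."""
    cfg = config or FeatureConfig()
    out: dict[str, float] = {}
    for img in region.channels:
        prefix = CHANNEL_PREFIXES[img.channel]
        d = denoise(img, window=cfg.denoise_window)
        morph = morphology_features(
            d, r_min=cfg.fft_r_min, r_max_frac=cfg.fft_r_max_frac,
            window=cfg.fft_window, min_length_px=cfg.trace_min_length_px)
        hist = histogram_features(d)
        tex = glcm_features(glcm(d, levels=cfg.glcm_levels,
                                 distance=cfg.glcm_distance))
        values = (morph.density, morph.mean_length_px, morph.mean_width_px,
                  morph.alignment_k,
                  hist.mean_intensity, hist.std_intensity, hist.smoothness,
                  hist.skewness, hist.uniformity, hist.entropy_bits,
                  tex.contrast, tex.correlation, tex.energy, tex.homogeneity)
        for name, value in zip(PER_CHANNEL_NAMES, values):
            out[f"{prefix}-{name}"] = float(value)
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ParameterError(
            f"region {region.region_id!r} produced non-finite features: {bad}")
    return out


def aggregate_sample(region_features: list[dict[str, float]]) -> dict[str, float]:
    """Arithmetic feature-wise mean over a sample's regions."""
    if not region_features:
        raise ParameterError("cannot aggregate an empty region list")
    keys = list(region_features[0])
    return {k: float(np.mean([rf[k] for rf in region_features])) for k in keys}


def build_cohort_table(cohort: Cohort,
                       config: FeatureConfig | None = None) -> pd.DataFrame:
    """Extract and aggregate features for a whole cohort.

    Returns a DataFrame indexed by sample_id with ``class_label`` first and
    the 28 canonical feature columns after it.
    """
    rows = {}
    labels = {}
    for sample_id, class_label, regions in cohort:
        try:
            feats = aggregate_sample(
                [extract_region_features(r, config) for r in regions])
        except ParameterError as exc:
            raise ParameterError(f"sample {sample_id!r}: {exc}") from exc
        rows[sample_id] = feats
        labels[sample_id] = class_label
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]
    table.insert(0, LABEL_COLUMN, pd.Series(labels))
    table.index.name = "sample_id"
    return table


def validate_cohort_table(table: pd.DataFrame) -> None:
    if LABEL_COLUMN not in table.columns:
        raise ParameterError(f"feature table is missing the {LABEL_COLUMN!r} column")
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ParameterError(f"feature table is missing columns {missing}")
    bad_labels = set(table[LABEL_COLUMN]) - set(CLASS_LABELS)
    if bad_labels:
        raise ParameterError(f"feature table has unknown class labels {bad_labels}")
    values = table[FEATURE_NAMES].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = table.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ParameterError(f"non-finite feature values for samples {bad}")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="sample_id", float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="sample_id")
    validate_cohort_table(table)
    return table


def group_difference_test(table: pd.DataFrame, feature_name: str,
                          group_a: str, group_b: str) -> float:
    """Two-sided Mann-Whitney U p-value for one feature between two classes.

    The exact null distribution is used for combined n <= 20 without ties;
    the tie-corrected normal approximation otherwise.
    """
    validate_cohort_table(table)
    if feature_name not in FEATURE_NAMES:
        raise ParameterError(f"unknown feature {feature_name!r}")
    a = table.loc[table[LABEL_COLUMN] == group_a, feature_name].to_numpy()
    b = table.loc[table[LABEL_COLUMN] == group_b, feature_name].to_numpy()
    if len(a) < 1 or len(b) < 1:
        raise ParameterError(
            f"both groups must be nonempty ({group_a}: {len(a)}, "
            f"{group_b}: {len(b)})")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(result.pvalue, 1.0))
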