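"""Shared fixtures: small rendered scenes and cohort feature tables.

The default-design cohort (34 samples at 512 px) is expensive, so it is
built once per session; smaller cohorts for smoke/property tests use
reduced designs with scaled-down fiber geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

import scarmorph as sm
from scarmorph.features import build_cohort_table
from scarmorph.images import ChannelImage
from scarmorph.simulate import CohortDesign, FiberClassParams


def small_presets(bit_depth: int = 8) -> dict:
    """Class presets scaled for 160-px test images (same qualitative order)."""
    def p(label, **kw):
        return FiberClassParams(class_label=label, bit_depth=bit_depth, **kw)

    return {
        "normal": {
            "collagen": p("normal", n_fibers=25, length_mean=70, length_sd=12,
                          width_mean=3, dispersion_k=2.0, intensity_mean=150,
                          intensity_sd=25, noise_sd=10),
            "elastin": p("normal", n_fibers=20, length_mean=60, length_sd=12,
                         width_mean=2, dispersion_k=1.8, intensity_mean=120,
                         intensity_sd=25, noise_sd=10),
        },
        "scar": {
            "collagen": p("scar", n_fibers=50, length_mean=25, length_sd=6,
                          width_mean=2, dispersion_k=0.6, intensity_mean=130,
                          intensity_sd=30, noise_sd=12),
            "elastin": p("scar", n_fibers=40, length_mean=20, length_sd=5,
                         width_mean=2, dispersion_k=0.5, intensity_mean=100,
                         intensity_sd=25, noise_sd=12),
        },
        "adjacent": {
            "collagen": p("adjacent", n_fibers=30, length_mean=60, length_sd=10,
                          width_mean=3, dispersion_k=7.0, intensity_mean=150,
                          intensity_sd=25, noise_sd=10),
            "elastin": p("adjacent", n_fibers=25, length_mean=55, length_sd=10,
                         width_mean=2, dispersion_k=6.0, intensity_mean=115,
                         intensity_sd=25, noise_sd=10),
        },
    }


def small_design(master_seed: int = 0, **overrides) -> CohortDesign:
    kwargs = dict(n_scar_sections=3, n_normal_sections=3,
                  n_adjacent_specimens=3, regions_min=2, regions_max=2,
                  image_size=160, class_params=small_presets(),
                  master_seed=master_seed)
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return sm.generate_cohort(small_design(master_seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_cohort_table(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-scale cohort: 16 scar + 10 normal + 8 adjacent samples."""
    return sm.generate_cohort(CohortDesign(master_seed=1))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return build_cohort_table(default_cohort)


def flat_image(value: int = 0, size: int = 64, channel: str = "collagen",
               bit_depth: int = 8) -> ChannelImage:
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return ChannelImage(np.full((size, size), value, dtype=dtype),
                        bit_depth=bit_depth, channel=channel)


def alignment_bench_params(k: float, mu: float, **kw) -> FiberClassParams:
    """Alignment-benchmark scene: straight, equal-weight, noise-free fibers.

    Under these conditions the generating concentration is unconfounded
    ground truth for the orientation analysis (no curvature smearing, no
    per-fiber weight variance, no noise floor).
    """
    base = dict(class_label="normal", n_fibers=150, length_mean=300,
                length_sd=0.0, width_mean=2, dispersion_k=k,
                mean_orientation=mu, intensity_mean=180, intensity_sd=0.0,
                noise_sd=0.0, background_level=5, curvature=0.0)
    base.update(kw)
    return FiberClassParams(**base)


@pytest.fixture(scope="session")
def k_recovery_medians():
    """Median fitted alignment k over 10 benchmark scenes per generating k."""
    medians = {}
    for k in (1.0, 2.0, 4.0, 8.0):
        vals = []
        for s in range(10):
            img = sm.render_fiber_image(
                alignment_bench_params(k, float((s * 37) % 180)), 512,
                seed=100 + s)
            dist = sm.orientation_distribution(sm.denoise(img))
            vals.append(sm.fit_von_mises(dist).k)
        medians[k] = float(np.median(vals))
    return medians
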