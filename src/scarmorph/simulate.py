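"""Synthetic paired collagen/elastin fiber images and full study cohorts.

The simulator emulates the qualitative class structure seen in multiphoton
images of human skin: *normal* dermis shows long, continuous, moderately
ordered fibers; *keloid scar* shows short, discrete, disordered fibers; the
*adjacent* scar-normal border shows a highly ordered (nearly parallel)
arrangement.  Fibers are drawn as anti-aliased thick polylines with small
random curvature; their in-plane orientations follow a semicircular von Mises
law realized through the doubled-angle construction, matching the model the
morphology module fits back.

Nothing here attempts SHG/TPEF physics — no point-spread function, cells or
depth sectioning; the goal is a scene whose *measurable* morphology and
texture carry the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .images import (CLASS_LABELS, ChannelImage, Cohort, RegionRecord,
                     write_cohort)

__all__ = [
    "FiberClassParams", "CohortDesign", "default_presets",
    "sample_orientations", "render_fiber_image", "render_region",
    "generate_cohort", "write_cohort",
]


def derive_seed(*key: int) -> int:
    """Map an integer key path to a 31-bit stream seed.

    The counter scheme: every sample/region/channel seed is
    ``SeedSequence([k0, k1, ...])`` of its position in the cohort tree, so
    streams are independent and any subtree is reproducible in isolation.
    """
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


@dataclass(frozen=True)
class FiberClassParams:
    """Rendering parameters for one tissue class and channel.

    ``dispersion_k`` is the concentration of the semicircular von Mises
    orientation law (doubled-angle convention): k=0 is isotropic, larger k
    means better aligned fibers.  Intensities and noise are in gray levels of
    the declared bit depth.
    """

    class_label: str
    n_fibers: int
    length_mean: float
    length_sd: float
    width_mean: float
    dispersion_k: float
    mean_orientation: float = 90.0
    fill_fraction_target: float = 1.0
    intensity_mean: float = 150.0
    intensity_sd: float = 25.0
    noise_sd: float = 10.0
    background_level: float = 8.0
    curvature: float = 0.08
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {self.class_label!r}")
        if self.n_fibers < 0:
            raise ParameterError("n_fibers must be nonnegative")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ParameterError("length_mean must be > 0, length_sd >= 0")
        if self.width_mean < 1:
            raise ParameterError("width_mean must be >= 1 pixel")
        if self.dispersion_k < 0:
            raise ParameterError("dispersion_k must be nonnegative")
        if not 0.0 <= self.mean_orientation < 180.0:
            raise ParameterError("mean_orientation must lie in [0, 180)")
        if not 0.0 <= self.fill_fraction_target <= 1.0:
            raise ParameterError("fill_fraction_target must lie in [0, 1]")
        if self.noise_sd < 0 or self.intensity_sd < 0:
            raise ParameterError("noise_sd and intensity_sd must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")


def sample_orientations(n: int, mean_deg: float, kappa: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw n fiber angles in [0, 180) deg from a semicircular von Mises law.

    Uses the doubled-angle trick: sample psi ~ vonMises(2*mu, kappa) on the
    full circle and return psi/2 folded to the semicircle.  kappa=0 reduces
    to the uniform law on [0, 180).
    """
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    psi = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return np.rad2deg(psi / 2.0) % 180.0


def _quadratic_bezier(p0, p1, p2, n_pts):
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


#: Internal rendering oversampling factor.  Spines are drawn on a grid this
#: many times finer than the target image and box-filtered down, which
#: anti-aliases oblique fibers properly (integer rasterization of oblique
#: lines otherwise scatters spectral power into a staircase pattern that
#: biases downstream orientation analysis).
SUPERSAMPLE = 3


def render_fiber_image(params: FiberClassParams, size: int,
                       seed: int | None = None) -> ChannelImage:
    """Render one synthetic fiber channel image of ``size`` x ``size`` pixels.

    Each fiber is a quadratic-Bezier spine (3 control points, curvature
    bounded by ``params.curvature`` of the fiber length) dilated to the class
    width, drawn on a supersampled grid and box-filtered down for
    anti-aliasing.  Per-fiber intensity is Gaussian, the whole frame gets
    additive Gaussian background noise, and the result is clipped and
    quantized to the bit depth.

    Fibers are added until ``n_fibers`` are drawn or the estimated foreground
    fill reaches ``fill_fraction_target``, whichever comes first.
    """
    if size < 64:
        raise ParameterError(f"image size must be >= 64 pixels, got {size}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    max_val = 2 ** params.bit_depth - 1
    scale = SUPERSAMPLE
    ss = size * scale

    spine = np.zeros((ss, ss), dtype=float)
    spine_px = 0
    for _ in range(params.n_fibers):
        fill_est = spine_px * params.width_mean * scale / (ss * ss)
        if fill_est >= params.fill_fraction_target:
            break
        theta = np.deg2rad(sample_orientations(
            1, params.mean_orientation, params.dispersion_k, rng)[0])
        length = max(4.0, rng.normal(params.length_mean, params.length_sd)) * scale
        center = rng.uniform(0.0, size, size=2) * scale  # (row, col)
        d = np.array([-np.sin(theta), np.cos(theta)])    # row decreases upward
        perp = np.array([-d[1], d[0]])
        bow = params.curvature * length * rng.uniform(-1.0, 1.0)
        p0 = center - d * length / 2.0
        p2 = center + d * length / 2.0
        p1 = center + perp * bow
        pts = _quadratic_bezier(p0, p1, p2, int(2 * length) + 2)
        rows = np.rint(pts[:, 0]).astype(int)
        cols = np.rint(pts[:, 1]).astype(int)
        keep = (rows >= 0) & (rows < ss) & (cols >= 0) & (cols < ss)
        rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            continue
        intensity = float(np.clip(
            rng.normal(params.intensity_mean, params.intensity_sd), 1.0, max_val))
        spine_px += int(np.count_nonzero(spine[rows, cols] == 0))
        np.maximum.at(spine, (rows, cols), intensity)

    if spine.any():
        dist, (ir, ic) = ndimage.distance_transform_edt(
            spine == 0, return_indices=True)
        radius = max(params.width_mean * scale / 2.0, 0.5 * scale)
        alpha = np.clip(radius + 0.5 * scale - dist, 0.0, scale) / scale
        fibers = (spine[ir, ic] * alpha).reshape(
            size, scale, size, scale).mean(axis=(1, 3))
    else:
        fibers = np.zeros((size, size), dtype=float)

    img = np.maximum(fibers, params.background_level)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, max_val)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return ChannelImage(img.astype(dtype), bit_depth=params.bit_depth)


def render_region(collagen_params: FiberClassParams,
                  elastin_params: FiberClassParams,
                  size: int,
                  region_seed: int = 0,
                  region_id: str = "r1",
                  randomize_orientation: bool = False) -> RegionRecord:
    """Render a paired collagen+elastin region.

    The two channels get independent streams derived from ``region_seed``.
    With ``randomize_orientation`` the region's dominant fiber direction is
    drawn uniformly and shared by both channels (collagen and elastin bundles
    co-orient in tissue).
    """
    if collagen_params.class_label != elastin_params.class_label:
        raise ParameterError("channel parameter sets must share a class label")
    if randomize_orientation:
        mu = float(np.random.default_rng(derive_seed(region_seed, 2)).uniform(0, 180))
        collagen_params = replace(collagen_params, mean_orientation=mu)
        elastin_params = replace(elastin_params, mean_orientation=mu)
    cimg = render_fiber_image(collagen_params, size, seed=derive_seed(region_seed, 0))
    eimg = render_fiber_image(elastin_params, size, seed=derive_seed(region_seed, 1))
    return RegionRecord(
        collagen=replace(cimg, channel="collagen"),
        elastin=replace(eimg, channel="elastin"),
        region_id=region_id,
    )


def default_presets(bit_depth: int = 8) -> dict[str, dict[str, FiberClassParams]]:
    """Per-class, per-channel rendering presets.

    Calibrated only to the qualitative contrasts reported for keloid tissue:
    scar fibers are short, discrete and disordered (smallest k, shortest
    length); adjacent-region fibers are highly ordered (largest k); normal
    fibers are long and continuous.  Elastin fibers are rendered thinner and
    dimmer than collagen, as in TPEF imagery.
    """
    def p(label, channel_kwargs):
        return FiberClassParams(class_label=label, bit_depth=bit_depth,
                                **channel_kwargs)

    return {
        "normal": {
            "collagen": p("normal", dict(n_fibers=70, length_mean=180, length_sd=35,
                                         width_mean=4, dispersion_k=2.0,
                                         intensity_mean=150, intensity_sd=25,
                                         noise_sd=10)),
            "elastin": p("normal", dict(n_fibers=60, length_mean=160, length_sd=35,
                                        width_mean=3, dispersion_k=1.8,
                                        intensity_mean=120, intensity_sd=25,
                                        noise_sd=10)),
        },
        "scar": {
            "collagen": p("scar", dict(n_fibers=140, length_mean=55, length_sd=15,
                                       width_mean=3, dispersion_k=0.6,
                                       intensity_mean=130, intensity_sd=30,
                                       noise_sd=12)),
            "elastin": p("scar", dict(n_fibers=110, length_mean=45, length_sd=12,
                                      width_mean=2, dispersion_k=0.5,
                                      intensity_mean=100, intensity_sd=25,
                                      noise_sd=12)),
        },
        "adjacent": {
            "collagen": p("adjacent", dict(n_fibers=80, length_mean=150, length_sd=30,
                                           width_mean=4, dispersion_k=7.0,
                                           intensity_mean=150, intensity_sd=25,
                                           noise_sd=10)),
            "elastin": p("adjacent", dict(n_fibers=70, length_mean=140, length_sd=30,
                                          width_mean=3, dispersion_k=6.0,
                                          intensity_mean=115, intensity_sd=25,
                                          noise_sd=10)),
        },
    }


@dataclass(frozen=True)
class CohortDesign:
    """Study design for a simulated cohort.

    Defaults mirror the source study design: 16 scar and 10 normal tissue
    sections plus adjacent regions from 8 scar specimens, with 2-3 imaged
    regions per section that are averaged per sample downstream.
    """

    n_scar_sections: int = 16
    n_normal_sections: int = 10
    n_adjacent_specimens: int = 8
    regions_min: int = 2
    regions_max: int = 3
    image_size: int = 512
    class_params: Mapping[str, Mapping[str, FiberClassParams]] = field(
        default_factory=default_presets)
    master_seed: int = 0
    randomize_orientation: bool = True

    def __post_init__(self) -> None:
        counts = (self.n_scar_sections, self.n_normal_sections,
                  self.n_adjacent_specimens)
        if any(c < 0 for c in counts):
            raise ParameterError("section counts must be nonnegative")
        if all(c == 0 for c in counts):
            raise ParameterError("at least one class must have samples")
        if not 1 <= self.regions_min <= self.regions_max:
            raise ParameterError("need 1 <= regions_min <= regions_max")
        missing = [c for c in CLASS_LABELS if c not in self.class_params]
        if missing:
            raise ParameterError(f"class_params missing presets for {missing}")


_CLASS_INDEX = {"scar": 0, "normal": 1, "adjacent": 2}


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate the full labelled cohort of a design.

    Returns ``[(sample_id, class_label, [RegionRecord, ...]), ...]``.  Every
    stream seed derives from ``master_seed`` through the documented
    (class, sample, region) counter scheme, so the cohort is a pure function
    of the design.
    """
    cohort: Cohort = []
    plan = (("scar", design.n_scar_sections),
            ("normal", design.n_normal_sections),
            ("adjacent", design.n_adjacent_specimens))
    for label, count in plan:
        ci = _CLASS_INDEX[label]
        presets = design.class_params[label]
        for j in range(count):
            sample_id = f"{label}_{j + 1:02d}"
            rng = np.random.default_rng(
                derive_seed(design.master_seed, ci, j))
            n_regions = int(rng.integers(design.regions_min,
                                         design.regions_max + 1))
            regions = []
            for r in range(n_regions):
                regions.append(render_region(
                    presets["collagen"], presets["elastin"],
                    design.image_size,
                    region_seed=derive_seed(design.master_seed, ci, j, r),
                    region_id=f"r{r + 1}",
                    randomize_orientation=design.randomize_orientation))
            cohort.append((sample_id, label, regions))
    return cohort
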