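"""Channel images, cohort manifests, and denoising.

A *channel image* is one single-channel grayscale frame from a multiphoton
acquisition: the SHG signal gives the collagen channel, the TPEF signal the
elastin channel.  A *region record* pairs the two channels imaged at the same
tissue location.  Cohorts live on disk as one directory per sample holding
``<region>_{collagen,elastin}.tif`` plus a ``manifest.csv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .errors import ImageFormatError, ManifestError, ParameterError

CHANNELS = ("collagen", "elastin")
CLASS_LABELS = ("normal", "scar", "adjacent")

#: Default physical pixel size: a 210 um field of view sampled at 512 px.
DEFAULT_PIXEL_SIZE_UM = 210.0 / 512.0

MANIFEST_COLUMNS = ("sample_id", "class_label", "region_id",
                    "collagen_path", "elastin_path")


@dataclass(frozen=True, eq=False)
class ChannelImage:
    """One grayscale image with channel tag and pixel-size metadata.

    Pixels are stored as an unsigned integer array; all values must fit the
    declared bit depth.  ``pixel_size_um`` is metadata only — every feature
    downstream is reported in pixels.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    channel: str = "collagen"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ImageFormatError(
                f"channel image must be a nonempty 2-D array, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channel not in CHANNELS:
            raise ParameterError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError(f"pixel dtype must be integer, got {px.dtype}")
        if px.min() < 0 or px.max() >= 2 ** self.bit_depth:
            raise ImageFormatError(
                f"pixel values must lie in [0, 2^{self.bit_depth}); "
                f"got range [{px.min()}, {px.max()}]")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True, eq=False)
class RegionRecord:
    """Paired collagen + elastin images for one imaged region of one sample."""

    collagen: ChannelImage
    elastin: ChannelImage
    region_id: str = "r1"

    def __post_init__(self) -> None:
        if self.collagen.channel != "collagen" or self.elastin.channel != "elastin":
            raise ParameterError("region channels must be tagged collagen/elastin")
        if self.collagen.shape != self.elastin.shape:
            raise ParameterError(
                f"region {self.region_id!r}: channel shapes differ "
                f"({self.collagen.shape} vs {self.elastin.shape})")

    @property
    def channels(self) -> tuple[ChannelImage, ChannelImage]:
        return self.collagen, self.elastin


def _dtype_for(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def read_channel_image(path: str | Path, channel: str,
                       pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ChannelImage:
    """Load a single-channel TIFF or PNG losslessly.

    Bit depth is inferred from the file's sample format; multi-channel files
    are rejected rather than silently flattened.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ImageFormatError(f"unsupported image format {suffix!r}: {path}")
    if arr.ndim != 2:
        raise ImageFormatError(
            f"expected a single-channel image, got shape {arr.shape}: {path}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ImageFormatError(f"unsupported pixel dtype {arr.dtype}: {path}")
    return ChannelImage(arr, bit_depth=depth, channel=channel,
                        pixel_size_um=pixel_size_um)


def write_channel_image(img: ChannelImage, path: str | Path) -> None:
    """Write a channel image as single-channel TIFF or PNG."""
    path = Path(path)
    arr = img.pixels.astype(_dtype_for(img.bit_depth))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise ImageFormatError(f"unsupported image format {suffix!r}: {path}")


def denoise(img: ChannelImage, window: int | None = 3) -> ChannelImage:
    """Median-filter an image (edge-replicated borders).

    ``window=None`` (or ``<= 1``) disables filtering.  The shot noise of
    photon-counting detectors is impulsive, which a small median removes
    without blurring fiber edges the way a Gaussian would.
    """
    if window is None or window <= 1:
        return img
    if window % 2 == 0:
        raise ParameterError(f"median window must be odd, got {window}")
    filtered = ndimage.median_filter(img.pixels, size=window, mode="nearest")
    return replace(img, pixels=filtered)


# ---------------------------------------------------------------------------
# cohort manifests

Cohort = list[tuple[str, str, list[RegionRecord]]]


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as ``<outdir>/<sample_id>/<region>_{channel}.tif`` + manifest.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample_id, class_label, regions in cohort:
        sample_dir = outdir / sample_id
        sample_dir.mkdir(exist_ok=True)
        for region in regions:
            cpath = sample_dir / f"{region.region_id}_collagen.tif"
            epath = sample_dir / f"{region.region_id}_elastin.tif"
            write_channel_image(region.collagen, cpath)
            write_channel_image(region.elastin, epath)
            rows.append((sample_id, class_label, region.region_id,
                         cpath.relative_to(outdir).as_posix(),
                         epath.relative_to(outdir).as_posix()))
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load and validate a cohort from its ``manifest.csv``.

    Paths in the manifest are resolved relative to the manifest's directory.
    Samples are returned in order of first appearance.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(MANIFEST_COLUMNS) <= set(reader.fieldnames):
            raise ManifestError(
                f"manifest must have columns {MANIFEST_COLUMNS}, "
                f"got {reader.fieldnames}")
        rows = list(reader)
    if not rows:
        raise ManifestError(f"manifest is empty: {manifest_path}")

    samples: dict[str, tuple[str, list[RegionRecord]]] = {}
    for i, row in enumerate(rows, start=2):  # header is line 1
        label = row["class_label"]
        if label not in CLASS_LABELS:
            raise ManifestError(
                f"line {i} ({row['sample_id']!r}): unknown class label {label!r}; "
                f"expected one of {CLASS_LABELS}")
        for col in ("collagen_path", "elastin_path"):
            if not row[col]:
                raise ManifestError(
                    f"line {i} ({row['sample_id']!r}): region {row['region_id']!r} "
                    f"is missing its {col}")
        try:
            region = RegionRecord(
                collagen=read_channel_image(root / row["collagen_path"], "collagen"),
                elastin=read_channel_image(root / row["elastin_path"], "elastin"),
                region_id=row["region_id"],
            )
        except (ImageFormatError, ParameterError) as exc:
            raise ManifestError(f"line {i} ({row['sample_id']!r}): {exc}") from exc
        if row["sample_id"] in samples:
            prev_label, regions = samples[row["sample_id"]]
            if prev_label != label:
                raise ManifestError(
                    f"line {i}: sample {row['sample_id']!r} has conflicting "
                    f"labels {prev_label!r} and {label!r}")
            regions.append(region)
        else:
            samples[row["sample_id"]] = (label, [region])
    return [(sid, label, regions) for sid, (label, regions) in samples.items()]
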