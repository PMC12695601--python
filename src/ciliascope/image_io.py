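"""Reading and writing of external formats.

Microscopy frames arrive as 16- or 24-bit RGB TIFFs (blue = DNA
counterstain, green/red = ciliary membrane marker).  Ground-truth instance
masks are stored as ``.npy`` integer label images (0 = background).
Feature tables are written as plain CSV, annotated overlays as PNG/TIFF.

Intensities are normalized by the *dtype* maximum (255 or 65535), not the
per-image maximum, so that thresholds remain comparable across images.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .errors import ChannelLayoutError, UnsupportedFormatError

#: Names of the RGB planes, in storage order.
CHANNEL_NAMES = ("red", "green", "blue")

#: Channel specifications accepted by :func:`extract_channel`.
CHANNEL_SPECS = ("red", "green", "blue", "red+green")


@dataclass
class RGBImage:
    """A normalized 3-channel fluorescence image.

    Attributes
    ----------
    pixels
        ``(H, W, 3)`` float array with intensities in ``[0, 1]``,
        channels ordered red, green, blue.
    original_dtype
        The integer dtype of the source file (``uint8`` for 24-bit RGB,
        ``uint16`` for 16-bit-per-channel scans); used to quantize on write.
    """

    pixels: np.ndarray
    original_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint16))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ChannelLayoutError(
                f"expected an (H, W, 3) array, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("RGBImage intensities must lie in [0, 1]")
        self.original_dtype = np.dtype(self.original_dtype)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one named plane as an ``(H, W)`` gray image."""
        return extract_channel(self, name)


def _check_tiff_extension(path: str | os.PathLike) -> Path:
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise UnsupportedFormatError(
            f"only '.tif' and '.tiff' image formats are supported, got {path.name!r}"
        )
    return path


def read_rgb_image(path: str | os.PathLike) -> RGBImage:
    """Read a TIFF image and normalize it to an :class:`RGBImage`.

    Single-plane (grayscale) TIFFs are broadcast to three identical
    channels.  Integer intensities are divided by the dtype maximum.
    """
    path = _check_tiff_extension(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw, raw, raw], axis=-1)
    if raw.ndim != 3:
        raise ChannelLayoutError(f"cannot interpret array of shape {raw.shape} as RGB")
    # channels-first layouts (C, H, W) with small leading axis
    if raw.shape[0] in (1, 3) and raw.shape[2] not in (1, 3):
        raw = np.moveaxis(raw, 0, -1)
    if raw.shape[2] == 1:
        raw = np.repeat(raw, 3, axis=2)
    if raw.shape[2] != 3:
        raise ChannelLayoutError(
            f"expected 1 or 3 channels, got {raw.shape[2]} (shape {raw.shape})"
        )
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        pixels = raw.astype(np.float64) / scale
        dtype = raw.dtype
    else:  # float TIFFs are taken to be already normalized
        pixels = np.clip(raw.astype(np.float64), 0.0, 1.0)
        dtype = np.dtype(np.uint16)
    return RGBImage(pixels=pixels, original_dtype=np.dtype(dtype))


def write_rgb_image(img: RGBImage, path: str | os.PathLike) -> None:
    """Write an :class:`RGBImage` back to TIFF at its recorded bit depth."""
    path = _check_tiff_extension(path)
    scale = float(np.iinfo(img.original_dtype).max)
    quantized = np.round(img.pixels * scale).astype(img.original_dtype)
    tifffile.imwrite(path, quantized, photometric="rgb")


def extract_channel(img: RGBImage, channel_spec: str) -> np.ndarray:
    """Extract one gray plane from an RGB image.

    ``"red+green"`` combines the two cilia-marker channels by pixel-wise
    maximum, which preserves the ``[0, 1]`` range.
    """
    if channel_spec not in CHANNEL_SPECS:
        from .errors import ConfigurationError

        raise ConfigurationError(
            f"unknown channel spec {channel_spec!r}; expected one of {CHANNEL_SPECS}"
        )
    if channel_spec == "red+green":
        return np.maximum(img.pixels[:, :, 0], img.pixels[:, :, 1])
    return img.pixels[:, :, CHANNEL_NAMES.index(channel_spec)].copy()


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an instance label map from ``.npy``.

    Accepts either a 2-D integer label image or a stacked ``(N, H, W)``
    array of binary per-instance masks; the latter is flattened to a label
    map by slice index + 1.
    """
    arr = np.load(path)
    if arr.ndim == 2:
        return arr.astype(np.int64)
    if arr.ndim == 3:
        labels = np.zeros(arr.shape[1:], dtype=np.int64)
        for i, plane in enumerate(arr):
            labels[plane > 0] = i + 1
        return labels
    raise ChannelLayoutError(f"cannot interpret mask array of shape {arr.shape}")


def write_label_mask(labels: np.ndarray, path: str | os.PathLike) -> None:
    np.save(path, np.asarray(labels, dtype=np.int64))


def write_cilia_features_csv(
    records: Sequence,
    path: str | os.PathLike,
    features: Sequence[str] | None = None,
    image_ids: Sequence[str] | None = None,
) -> None:
    """Write one row per detected cilium.

    Columns are the configured feature list (in order) prefixed by an
    ``image`` identifier column and the instance id.
    """
    from .config import DEFAULT_CILIA_FEATURES

    features = list(features if features is not None else DEFAULT_CILIA_FEATURES)
    if image_ids is None:
        image_ids = [""] * len(records)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "instance_id", *features])
        for image_id, rec in zip(image_ids, records):
            writer.writerow(
                [image_id, rec.instance_id, *(getattr(rec, name) for name in features)]
            )


#: Column order of the per-image summary table.
SUMMARY_COLUMNS = (
    "nuclei_number",
    "area_of_nuclei_pct",
    "individual_nucleus_area_ratio_pct",
    "cilia_number",
    "pct_cilia_within_cells",
    "mean_nearest_center_mass_distance",
    "mean_nearest_boundary_distance",
)


def write_image_summary_csv(
    summaries: Iterable, path: str | os.PathLike, image_ids: Sequence[str] | None = None
) -> None:
    """Write one row of aggregated features per image."""
    summaries = list(summaries)
    if image_ids is None:
        image_ids = [""] * len(summaries)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", *SUMMARY_COLUMNS])
        for image_id, summ in zip(image_ids, summaries):
            row = [getattr(summ, name) for name in SUMMARY_COLUMNS]
            writer.writerow([image_id, *("" if v is None else v for v in row)])


def render_overlay(
    img: RGBImage,
    cilia: Sequence,
    nuclei_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Draw detection results on top of the image.

    Each cilium gets an orange bounding box with its skeleton length
    annotated beside it; nucleus instance outlines are drawn in red.
    Returns an ``(H, W, 3)`` uint8 array.
    """
    base = np.round(img.pixels * 255.0).astype(np.uint8)
    if nuclei_labels is not None and nuclei_labels.max() > 0:
        from skimage.segmentation import find_boundaries

        outlines = find_boundaries(nuclei_labels, mode="outer")
        base[outlines] = (255, 60, 60)
    pil = Image.fromarray(base)
    draw = ImageDraw.Draw(pil)
    orange = (255, 165, 0)
    for rec in cilia:
        min_r, min_c, max_r, max_c = rec.bounding_box
        draw.rectangle([min_c - 1, min_r - 1, max_c, max_r], outline=orange)
        draw.text((min_c, max_r + 1), f"{rec.skeleton_length:.1f}", fill=orange)
    return np.asarray(pil)
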