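"""Nuclei segmentation branch.

Images are resized to 512x512 before segmentation and the resulting label
map is mapped back to original coordinates afterwards.  The segmentation
backend is pluggable: any object with a ``segment(gray) -> (labels,
flow_errors)`` method operating at 512x512 can be used, so a trained
flow-based model can be dropped in.  The shipped default is a
deterministic classical watershed baseline (Gaussian smoothing, Otsu
threshold, hole filling, distance-transform maxima, marker watershed),
which needs no trained weights.

Instances whose reported flow error exceeds ``CELLPOSE_FLOW_THRESHOLD``
are discarded; the baseline backend reports zero flow error for every
instance, so the threshold has no effect on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation, transform

from .config import DetectionConfig
from .errors import CiliascopeError
from .image_io import RGBImage, extract_channel

#: Working resolution of the segmentation backends.
SEGMENTATION_SIZE = (512, 512)


@dataclass
class NucleusRecord:
    """One segmented nucleus, in original-image coordinates."""

    instance_id: int
    pixel_count: int
    centroid: tuple[float, float]  # (row, col)
    touches_edge: bool
    equivalent_diameter: float  # diameter of the equal-area circle
    pixel_coords: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class ScaleRecord:
    """Remembers the original shape for the inverse resize."""

    original_shape: tuple[int, int]
    target_shape: tuple[int, int] = SEGMENTATION_SIZE


@runtime_checkable
class SegmentationBackend(Protocol):
    name: str

    def segment(self, gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Segment a 512x512 gray image; return (labels, per-instance flow errors)."""


def resize_for_segmentation(gray: np.ndarray) -> tuple[np.ndarray, ScaleRecord]:
    """Bilinear resize to the 512x512 working resolution."""
    gray = np.asarray(gray, dtype=np.float64)
    record = ScaleRecord(original_shape=gray.shape)
    if gray.shape == SEGMENTATION_SIZE:
        return gray.copy(), record
    resized = transform.resize(
        gray,
        SEGMENTATION_SIZE,
        order=1,
        mode="reflect",
        anti_aliasing=gray.shape[0] > SEGMENTATION_SIZE[0],
        preserve_range=True,
    )
    return resized, record


@dataclass
class BaselineNucleiBackend:
    """Classical watershed segmentation of DNA-stained nuclei.

    Parameters are in 512x512 working-resolution pixels.  ``min_distance``
    is the minimum separation between watershed seed maxima; blobs whose
    distance transforms carry a single maximum stay whole, touching blobs
    with two maxima are split.
    """

    gauss_sigma: float = 2.0
    min_distance: int = 10
    peak_smooth_sigma: float = 1.5
    name: str = "classical-watershed"

    def segment(self, gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gray = np.asarray(gray, dtype=np.float64)
        smooth = filters.gaussian(gray, sigma=self.gauss_sigma, mode="reflect")
        empty = np.zeros(gray.shape, dtype=np.int64)
        if np.ptp(smooth) == 0:
            return empty, np.zeros(0)
        threshold = filters.threshold_otsu(smooth)
        binary = ndi.binary_fill_holes(smooth > threshold)
        if not binary.any():
            return empty, np.zeros(0)
        dist = ndi.distance_transform_edt(binary)
        # slight smoothing removes integer-EDT plateaus so each convex blob
        # keeps exactly one regional maximum
        dist_smooth = filters.gaussian(dist, sigma=self.peak_smooth_sigma)
        blob_labels = measure.label(binary)
        peaks = feature.peak_local_max(
            dist_smooth,
            min_distance=self.min_distance,
            labels=blob_labels,
            exclude_border=False,
        )
        markers = np.zeros(gray.shape, dtype=np.int64)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = blob_labels.astype(np.int64)
        else:
            labels = segmentation.watershed(-dist, markers, mask=binary).astype(np.int64)
        n = int(labels.max())
        return labels, np.zeros(n)


def postfilter_nuclei(
    labels: np.ndarray, min_size: int, exclude_edge: bool
) -> np.ndarray:
    """Drop instances below ``min_size`` pixels (strict) and, optionally,
    instances touching the border; relabel survivors consecutively from 1."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros_like(labels)
    if labels.max() == 0:
        return out
    counts = np.bincount(labels.ravel())
    border_ids: set[int] = set()
    if exclude_edge:
        for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
            border_ids.update(np.unique(edge).tolist())
    next_id = 1
    for instance_id in range(1, len(counts)):
        if counts[instance_id] == 0 or counts[instance_id] < min_size:
            continue
        if instance_id in border_ids:
            continue
        out[labels == instance_id] = next_id
        next_id += 1
    return out


def rescale_labels(labels: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor map of a label image back to original coordinates.

    Every input instance is guaranteed to survive with at least one pixel
    (relevant when the original frame is smaller than 512x512).
    """
    labels = np.asarray(labels, dtype=np.int64)
    if tuple(original_shape) == labels.shape:
        return labels.copy()
    out = transform.resize(
        labels, original_shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(np.int64)
    present = set(np.unique(out).tolist())
    scale = (original_shape[0] / labels.shape[0], original_shape[1] / labels.shape[1])
    for instance_id in np.unique(labels):
        if instance_id == 0 or instance_id in present:
            continue
        rows, cols = np.nonzero(labels == instance_id)
        r = min(original_shape[0] - 1, int(round(rows.mean() * scale[0])))
        c = min(original_shape[1] - 1, int(round(cols.mean() * scale[1])))
        out[r, c] = instance_id
    return out


def records_from_labels(labels: np.ndarray) -> list[NucleusRecord]:
    """Per-instance records for an existing label map."""
    labels = np.asarray(labels, dtype=np.int64)
    records = []
    for prop in measure.regionprops(labels):
        records.append(
            NucleusRecord(
                instance_id=int(prop.label),
                pixel_count=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                touches_edge=(
                    prop.bbox[0] == 0
                    or prop.bbox[1] == 0
                    or prop.bbox[2] == labels.shape[0]
                    or prop.bbox[3] == labels.shape[1]
                ),
                equivalent_diameter=float(prop.equivalent_diameter_area),
                pixel_coords=np.argwhere(labels == prop.label),
            )
        )
    return records


def labels_from_records(
    records: Sequence[NucleusRecord], shape: tuple[int, int]
) -> np.ndarray:
    """Rebuild a label map from nucleus records."""
    labels = np.zeros(shape, dtype=np.int64)
    for rec in records:
        labels[rec.pixel_coords[:, 0], rec.pixel_coords[:, 1]] = rec.instance_id
    return labels


def segment_nuclei(
    rgb: RGBImage,
    config: DetectionConfig | None = None,
    backend: SegmentationBackend | None = None,
) -> list[NucleusRecord]:
    """Run the full nuclei branch on one image.

    blue channel -> resize to 512x512 -> backend.segment -> flow-error
    filter -> size/edge post-filter -> rescale to original coordinates ->
    per-nucleus records.
    """
    config = config or DetectionConfig()
    backend = backend or BaselineNucleiBackend()
    gray = extract_channel(rgb, config.nuclei_channel)
    resized, scale = resize_for_segmentation(gray)
    try:
        labels, flow_errors = backend.segment(resized)
    except Exception as exc:  # surface backend failures with context
        raise CiliascopeError(f"segmentation backend {backend.name!r} failed: {exc}") from exc
    flow_errors = np.asarray(flow_errors, dtype=np.float64)
    for instance_id in range(1, int(labels.max()) + 1):
        if (
            instance_id <= len(flow_errors)
            and flow_errors[instance_id - 1] > config.CELLPOSE_FLOW_THRESHOLD
        ):
            labels = np.where(labels == instance_id, 0, labels)
    labels = postfilter_nuclei(labels, config.CELLPOSE_MIN_SIZE, config.EXCLUDE_EDGE_NUCLEI)
    labels = rescale_labels(labels, scale.original_shape)
    return records_from_labels(labels)
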