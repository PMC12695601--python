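"""Cilium candidate extraction, per-cilium geometry and refinement.

Candidates are the connected components of the pre-processed binary mask.
Each component is approximated by its moments-fitted ellipse (major/minor
axis, eccentricity) and described by area, Crofton perimeter, form factor
4*pi*A/P^2, and skeleton length — the geodesic diameter of its medial-axis
skeleton, which tracks bent or curved filaments better than the ellipse
major axis does.  Refinement keeps only candidates above configurable
minima for length, area, eccentricity and perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

from .config import DetectionConfig
from .image_io import RGBImage

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class CiliumRecord:
    """Geometry of one detected cilium (all lengths in pixels)."""

    instance_id: int
    area: float  # pixel count
    perimeter: float  # Crofton 4-direction estimate
    centroid: tuple[float, float]  # (row, col), sub-pixel
    eccentricity: float  # 0 = circle, 1 = line segment
    form_factor: float  # 4*pi*area / perimeter**2
    axis_minor_length: float
    axis_major_length: float
    skeleton_length: float  # geodesic length of the medial-axis centerline
    bounding_box: tuple[int, int, int, int]  # (min_r, min_c, max_r, max_c), half-open
    touches_edge: bool
    length_um: float | None = None  # skeleton length * pixel_size when configured
    pixel_coords: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class RefinementThresholds:
    """Inclusive minima used by the refinement filter."""

    min_length: float = 14.0
    min_area: float = 256.0
    min_eccentricity: float = 0.46
    min_perimeter: float = 67.0
    exclude_edge: bool = False
    length_measure: str = "skeleton"  # 'skeleton' or 'major_axis'

    @classmethod
    def from_config(cls, config: DetectionConfig) -> "RefinementThresholds":
        return cls(
            min_length=config.CILIA_MIN_LENGTH,
            min_area=config.CILIA_MIN_AREA,
            min_eccentricity=config.CILIA_MIN_ECCENTRICITY,
            min_perimeter=config.CILIA_MIN_PERIMETER,
            exclude_edge=config.EXCLUDE_EDGE_CILIA,
            length_measure=config.length_measure,
        )


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground components 1..K.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return measure.label(
        np.asarray(mask).astype(bool), connectivity=1 if connectivity == 4 else 2
    )


def _touches_edge(bbox: tuple[int, int, int, int], shape: tuple[int, int]) -> bool:
    min_r, min_c, max_r, max_c = bbox
    return min_r == 0 or min_c == 0 or max_r == shape[0] or max_c == shape[1]


def region_features(
    labels: np.ndarray, instance_id: int, compute_skeleton: bool = True
) -> CiliumRecord:
    """Compute the full per-cilium descriptor for one labeled instance."""
    region_mask = labels == instance_id
    if not region_mask.any():
        raise KeyError(f"instance id {instance_id} not present in label map")
    (prop,) = measure.regionprops(region_mask.astype(np.uint8))
    perimeter = float(prop.perimeter_crofton)
    area = float(prop.area)
    form_factor = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    bbox = tuple(int(v) for v in prop.bbox)
    sub = region_mask[bbox[0] : bbox[2], bbox[1] : bbox[3]]
    return CiliumRecord(
        instance_id=int(instance_id),
        area=area,
        perimeter=perimeter,
        centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
        eccentricity=float(prop.eccentricity),
        form_factor=float(form_factor),
        axis_minor_length=float(prop.axis_minor_length),
        axis_major_length=float(prop.axis_major_length),
        skeleton_length=skeleton_length(sub) if compute_skeleton else 0.0,
        bounding_box=bbox,
        touches_edge=_touches_edge(bbox, labels.shape),
        pixel_coords=np.argwhere(region_mask),
    )


def skeleton_length(region_mask: np.ndarray) -> float:
    """Length of a region's centerline in pixels.

    The medial-axis skeleton is treated as an 8-connected graph with edge
    weights 1 (orthogonal) and sqrt(2) (diagonal); the returned length is
    the longest shortest path between skeleton endpoints (pixels of degree
    one).  Cycles without endpoints fall back to the all-pairs geodesic
    diameter.  A single-pixel skeleton has length 0.
    """
    region_mask = np.asarray(region_mask).astype(bool)
    if not region_mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    # fixed rng: medial_axis breaks ties randomly unless seeded
    skel = morphology.medial_axis(np.pad(region_mask, 1), rng=0)
    coords = np.argwhere(skel)
    n = len(coords)
    if n <= 1:
        return 0.0
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    degree = np.zeros(n, dtype=int)
    for (r, c), i in index.items():
        for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(_SQRT2 if dr and dc else 1.0)
                degree[i] += 1
    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    endpoints = np.flatnonzero(degree == 1)
    if len(endpoints) < 2:
        endpoints = np.arange(n)
    dist = dijkstra(graph, directed=False, indices=endpoints)
    dist = dist[:, endpoints]
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def _length_of(record: CiliumRecord, measure_name: str) -> float:
    return record.skeleton_length if measure_name == "skeleton" else record.axis_major_length


def refine_candidates(
    records: Sequence[CiliumRecord],
    thresholds: RefinementThresholds,
    image_shape: tuple[int, int] | None = None,
) -> list[CiliumRecord]:
    """Keep candidates whose dimensions are consistent with primary cilia.

    A record is retained iff length >= min_length AND area >= min_area AND
    eccentricity >= min_eccentricity AND perimeter >= min_perimeter
    (all inclusive); with ``exclude_edge``, border-touching records are
    additionally dropped.  Pure filter: output order follows input.
    """
    kept = []
    for rec in records:
        if _length_of(rec, thresholds.length_measure) < thresholds.min_length:
            continue
        if rec.area < thresholds.min_area:
            continue
        if rec.eccentricity < thresholds.min_eccentricity:
            continue
        if rec.perimeter < thresholds.min_perimeter:
            continue
        if thresholds.exclude_edge and rec.touches_edge:
            continue
        kept.append(rec)
    return kept


def detect_cilia(rgb: RGBImage, config: DetectionConfig) -> list[CiliumRecord]:
    """Run the full cilia branch: pre-process, label, measure, refine."""
    from .preprocess import preprocess_cilia_channel

    mask = preprocess_cilia_channel(rgb, config)
    labels = label_components(mask, config.connectivity)
    records = [
        region_features(labels, instance_id)
        for instance_id in range(1, int(labels.max()) + 1)
    ]
    refined = refine_candidates(
        records, RefinementThresholds.from_config(config), labels.shape
    )
    if config.pixel_size is not None:
        refined = [
            replace(rec, length_um=rec.skeleton_length * config.pixel_size)
            for rec in refined
        ]
    return refined
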