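"""Per-image aggregated features combining both branches.

Seven characteristics describe one image: the nucleus count, the percent
of image area covered by nuclei (a confluence proxy), the mean nucleus
area as percent of image area (``area_of_nuclei_pct / nuclei_number``),
the cilium count, the fraction of cilia lying within cells, and the mean
distances from each cilium to its nearest nucleus (centroid-to-centroid
and boundary-to-boundary).

Cells themselves are not segmented — only nuclei are — so "within a cell"
is approximated by dilating the nucleus masks by a configurable radius
(default: the median nucleus equivalent diameter of the image, a proxy
for the cell-body extent) and testing the cilium centroid against that
union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import DetectionConfig
from .detect import CiliumRecord
from .nuclei import NucleusRecord


@dataclass
class ImageSummary:
    """The seven aggregated characteristics of one image.

    Distance and ratio fields are ``None`` (missing) when the instance
    set they need is empty.
    """

    nuclei_number: int
    area_of_nuclei_pct: float | None
    individual_nucleus_area_ratio_pct: float | None
    cilia_number: int
    pct_cilia_within_cells: float | None
    mean_nearest_center_mass_distance: float | None
    mean_nearest_boundary_distance: float | None


def boundary_pixels(coords: np.ndarray) -> np.ndarray:
    """4-connected inner boundary of a pixel set given as an (N, 2) array."""
    coords = np.asarray(coords)
    members = set(map(tuple, coords.tolist()))
    edge = [
        (r, c)
        for r, c in members
        if any((r + dr, c + dc) not in members for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)))
    ]
    return np.array(sorted(edge), dtype=np.int64).reshape(-1, 2)


def _nucleus_pixel_tree(nuclei: Sequence[NucleusRecord]) -> cKDTree:
    return cKDTree(np.vstack([rec.pixel_coords for rec in nuclei]))


def cilium_within_cell(
    cilium: CiliumRecord, nuclei: Sequence[NucleusRecord], radius: float
) -> bool:
    """True iff the cilium centroid lies in the union of nucleus masks
    dilated by ``radius`` (Euclidean)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not nuclei:
        return False
    tree = _nucleus_pixel_tree(nuclei)
    dist, _ = tree.query(np.asarray(cilium.centroid))
    return bool(dist <= radius)


def _default_within_radius(nuclei: Sequence[NucleusRecord]) -> float:
    return float(np.median([rec.equivalent_diameter for rec in nuclei]))


def summarize_image(
    nuclei: Sequence[NucleusRecord],
    cilia: Sequence[CiliumRecord],
    image_shape: tuple[int, int],
    config: DetectionConfig | None = None,
) -> ImageSummary:
    """Compute the aggregated characteristics for one image.

    All records must be in the same (original-image) coordinate frame.
    """
    config = config or DetectionConfig()
    total_px = float(image_shape[0] * image_shape[1])
    n_nuclei = len(nuclei)
    n_cilia = len(cilia)

    if n_nuclei:
        area_pct = 100.0 * sum(rec.pixel_count for rec in nuclei) / total_px
        individual_ratio = area_pct / n_nuclei
    else:
        area_pct = None
        individual_ratio = None

    pct_within = None
    mean_center = None
    mean_boundary = None
    if n_nuclei and n_cilia:
        radius = (
            config.within_cell_radius
            if config.within_cell_radius is not None
            else _default_within_radius(nuclei)
        )
        pixel_tree = _nucleus_pixel_tree(nuclei)
        centroids = np.array([rec.centroid for rec in cilia])
        dist_to_mask, _ = pixel_tree.query(centroids)
        pct_within = 100.0 * float(np.mean(dist_to_mask <= radius))

        nucleus_centroids = np.array([rec.centroid for rec in nuclei])
        center_tree = cKDTree(nucleus_centroids)
        center_dists, _ = center_tree.query(centroids)
        mean_center = float(np.mean(center_dists))

        boundary_tree = cKDTree(
            np.vstack([boundary_pixels(rec.pixel_coords) for rec in nuclei])
        )
        per_cilium = []
        for rec in cilia:
            cil_boundary = boundary_pixels(rec.pixel_coords)
            dists, _ = boundary_tree.query(cil_boundary)
            per_cilium.append(float(np.min(dists)))
        mean_boundary = float(np.mean(per_cilium))

    return ImageSummary(
        nuclei_number=n_nuclei,
        area_of_nuclei_pct=area_pct,
        individual_nucleus_area_ratio_pct=individual_ratio,
        cilia_number=n_cilia,
        pct_cilia_within_cells=pct_within,
        mean_nearest_center_mass_distance=mean_center,
        mean_nearest_boundary_distance=mean_boundary,
    )
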