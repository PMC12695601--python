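"""Cilia-channel enhancement and binarization.

The cilia branch of the pipeline enhances the marker channel and
binarizes it in a fixed order: CLAHE (local contrast), Gaussian smoothing
(background interference), white top-hat with a disk structuring element
(keeps thin bright filaments, corrects uneven illumination), then Yen's
entropic threshold.  All stages are shape-preserving and deterministic.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure, filters, morphology

from .config import DetectionConfig
from .errors import ConfigurationError
from .image_io import RGBImage, extract_channel


def clahe_enhance(
    gray: np.ndarray, clip_limit: float = 0.01, tile_grid: int = 8
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``tile_grid`` gives the number of tiles per axis; ``clip_limit`` is the
    fraction-of-histogram clipping convention.  A constant image is
    returned unchanged (no contrast to redistribute).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if np.ptp(gray) == 0:
        return gray.copy()
    kernel = (
        max(1, gray.shape[0] // tile_grid),
        max(1, gray.shape[1] // tile_grid),
    )
    out = exposure.equalize_adapthist(gray, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def gaussian_smooth(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian filtering with reflective boundaries, kernel cut at 4 sigma."""
    if sigma <= 0:
        raise ConfigurationError(f"gaussian sigma must be > 0, got {sigma}")
    return filters.gaussian(
        np.asarray(gray, dtype=np.float64), sigma=sigma, mode="reflect", truncate=4.0
    )


def tophat_filter(gray: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: image minus its opening with a disk of the given radius.

    Keeps bright structures thinner than the disk; the result is
    non-negative and pointwise bounded by the input.
    """
    if radius < 1:
        raise ConfigurationError(f"top-hat radius must be >= 1, got {radius}")
    footprint = morphology.disk(int(radius))
    return morphology.white_tophat(np.asarray(gray, dtype=np.float64), footprint)


def yen_threshold(gray: np.ndarray, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Yen's automatic threshold on the intensity histogram.

    Returns ``(threshold, mask)`` with ``mask = gray > threshold``
    (strictly above).  A constant image is degenerate: the threshold is
    that constant and the mask is empty.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if np.ptp(gray) == 0:
        return float(gray.flat[0]), np.zeros(gray.shape, dtype=bool)
    t = float(filters.threshold_yen(gray, nbins=nbins))
    return t, gray > t


def preprocess_cilia_channel(rgb: RGBImage, config: DetectionConfig) -> np.ndarray:
    """Full pre-processing composition for the cilia branch.

    channel selection -> CLAHE -> Gaussian(CILIA_GAUSS_SIGMA) ->
    top-hat(CILIA_TOPHAT_RADIUS) -> Yen threshold; returns the binary mask.
    """
    gray = extract_channel(rgb, config.CILIA_COLOR)
    gray = clahe_enhance(gray, config.clahe_clip_limit, config.clahe_tile_grid)
    gray = gaussian_smooth(gray, config.CILIA_GAUSS_SIGMA)
    gray = tophat_filter(gray, config.CILIA_TOPHAT_RADIUS)
    _, mask = yen_threshold(gray)
    return mask
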