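"""Folder-level workflow: run both branches, aggregate, write outputs.

``run_folder`` discovers every ``.tif``/``.tiff`` under a folder
(recursively), runs cilia detection and nuclei segmentation on each,
aggregates per-image features, and writes a per-cilium features CSV, a
per-image summary CSV, annotated overlays, and a JSON manifest.  One
failed image does not abort the run.  The whole pipeline is a pure
function of (input bytes, configuration): re-runs produce identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .aggregate import summarize_image
from .config import DetectionConfig
from .detect import detect_cilia
from .errors import CiliascopeError
from .image_io import (
    read_label_mask,
    read_rgb_image,
    render_overlay,
    write_cilia_features_csv,
    write_image_summary_csv,
)
from .metrics import DatasetSummary, MetricSet, dataset_summary, evaluate_masks
from .nuclei import BaselineNucleiBackend, labels_from_records, segment_nuclei

logger = logging.getLogger("ciliascope")


@dataclass
class ImageStatus:
    path: str
    status: str  # 'ok' or 'failed'
    reason: str = ""
    n_cilia: int = 0
    n_nuclei: int = 0


@dataclass
class RunManifest:
    input_folder: str
    images: list[ImageStatus] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def discover_images(folder: str | Path) -> list[Path]:
    folder = Path(folder)
    if not folder.is_dir():
        raise CiliascopeError(f"input folder does not exist: {folder}")
    found = sorted(
        p for p in folder.rglob("*") if p.suffix.lower() in (".tif", ".tiff")
    )
    if not found:
        raise CiliascopeError(f"no .tif/.tiff images found under {folder}")
    return found


def run_folder(
    folder: str | Path,
    config: DetectionConfig | None = None,
    backend=None,
    output_dir: str | Path | None = None,
) -> RunManifest:
    """Process every TIFF under ``folder``; write CSVs, overlays, manifest."""
    config = config or DetectionConfig()
    backend = backend or BaselineNucleiBackend()
    folder = Path(folder)
    output_dir = Path(output_dir) if output_dir is not None else folder / "cilia_output"
    output_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(input_folder=str(folder), config=config.to_dict())
    all_records, all_record_ids = [], []
    summaries, summary_ids = [], []
    for path in discover_images(folder):
        image_id = path.stem
        t0 = time.perf_counter()
        try:
            rgb = read_rgb_image(path)
            cilia = detect_cilia(rgb, config)
            nuclei = segment_nuclei(rgb, config, backend)
            summary = summarize_image(nuclei, cilia, rgb.shape, config)
            nuclei_labels = labels_from_records(nuclei, rgb.shape)
            overlay = render_overlay(rgb, cilia, nuclei_labels)
            overlay_path = output_dir / f"{image_id}_overlay.png"
            iio.imwrite(overlay_path, overlay)
            all_records.extend(cilia)
            all_record_ids.extend([image_id] * len(cilia))
            summaries.append(summary)
            summary_ids.append(image_id)
            manifest.images.append(
                ImageStatus(
                    path=str(path), status="ok", n_cilia=len(cilia), n_nuclei=len(nuclei)
                )
            )
            logger.info(
                "%s: %d cilia, %d nuclei (%.2f s)",
                image_id, len(cilia), len(nuclei), time.perf_counter() - t0,
            )
            if not cilia and not nuclei:
                logger.warning("%s: no objects detected (degenerate image?)", image_id)
        except Exception as exc:
            manifest.images.append(ImageStatus(path=str(path), status="failed", reason=str(exc)))
            logger.warning("%s: failed (%s)", image_id, exc)

    features_csv = output_dir / "CILIA_FEATURES.csv"
    summary_csv = output_dir / "image_summary.csv"
    write_cilia_features_csv(
        all_records, features_csv, features=config.CILIA_FEATURES, image_ids=all_record_ids
    )
    write_image_summary_csv(summaries, summary_csv, image_ids=summary_ids)
    manifest.outputs = {
        "features_csv": str(features_csv),
        "summary_csv": str(summary_csv),
        "output_dir": str(output_dir),
    }
    manifest_path = output_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def evaluate_against_truth(
    pred_folder: str | Path,
    gt_folder: str | Path,
    thresholds: Sequence[float] = (0.5,),
) -> dict:
    """Evaluate predicted ``.npy`` label masks against ground-truth masks.

    Folders are matched by file stem; unmatched stems on either side are
    an error.  Returns per-image metric sets plus the dataset summary.
    """
    pred_folder, gt_folder = Path(pred_folder), Path(gt_folder)
    pred_files = {p.stem: p for p in sorted(pred_folder.glob("*.npy"))}
    gt_files = {p.stem: p for p in sorted(gt_folder.glob("*.npy"))}
    unmatched = sorted(set(pred_files) ^ set(gt_files))
    if unmatched:
        raise CiliascopeError(f"unmatched mask filenames between folders: {unmatched}")
    if not pred_files:
        raise CiliascopeError("no .npy masks found to evaluate")

    per_image: dict[str, list[MetricSet]] = {}
    flat: list[MetricSet] = []
    for stem in sorted(pred_files):
        pred = read_label_mask(pred_files[stem])
        gt = read_label_mask(gt_files[stem])
        sets = evaluate_masks(pred, gt, thresholds)
        per_image[stem] = sets
        flat.extend(sets)
    summary: DatasetSummary = dataset_summary(flat)
    return {
        "per_image": {
            stem: [asdict(ms) for ms in sets] for stem, sets in per_image.items()
        },
        "summary": {
            "mean_ap": {str(t): v for t, v in summary.mean_ap.items()},
            "mean_abs_one_minus_cnr": summary.mean_abs_one_minus_cnr,
            "n_images": len(per_image),
        },
    }
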