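"""File interchange: image/mask pairs and localization report tables."""

from __future__ import annotations

import json
import math
import pathlib

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metrics import LocalizationReport
from .phantoms import ImageSample

IMAGE_EXTS = (".png", ".tif", ".tiff", ".npy")

REPORT_COLUMNS = [
    "sample_id",
    "lesion_id",
    "centroid_gt_y",
    "centroid_gt_x",
    "centroid_pred_y",
    "centroid_pred_x",
    "distance_px",
    "overlap_pct",
    "cropped_iou",
]


class UnreadableImageError(ValueError):
    pass


def _load_array(path: pathlib.Path) -> np.ndarray:
    try:
        if path.suffix == ".npy":
            return np.load(path)
        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - normalize into one error kind
        raise UnreadableImageError(f"cannot read {path}: {exc}") from exc


def _to_unit_range(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def read_image_mask_pair(path_stem: str | pathlib.Path) -> ImageSample:
    """Load ``<stem>.{png,tif,tiff,npy}`` + ``<stem>.mask.*`` as a sample.

    Integer images are scaled to [0, 1] by bit depth; floats pass through.
    The mask is binarized at > 0. A ``<stem>.json`` sidecar may supply
    patient_id and modality.
    """
    stem = pathlib.Path(path_stem)
    image_path = next(
        (stem.with_suffix(e) for e in IMAGE_EXTS if stem.with_suffix(e).exists()),
        None,
    )
    if image_path is None:
        raise FileNotFoundError(f"no image found for stem {stem}")
    mask_path = next(
        (
            stem.with_suffix(f".mask{e}")
            for e in IMAGE_EXTS
            if stem.with_suffix(f".mask{e}").exists()
        ),
        None,
    )
    if mask_path is None:
        raise FileNotFoundError(f"no mask found for stem {stem}")

    image = _to_unit_range(_load_array(image_path))
    mask = (_load_array(mask_path) > 0).astype(np.uint8)
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} shapes differ"
        )
    meta = {}
    sidecar = stem.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageSample(
        image=image,
        mask=mask,
        patient_id=meta.get("patient_id", stem.name),
        modality=meta.get("modality", "mammography"),
    )


def _report_row(sample_id: str, r: LocalizationReport) -> dict:
    return {
        "sample_id": sample_id,
        "lesion_id": r.lesion_id,
        "centroid_gt_y": round(r.centroid_gt.y_bar, 2),
        "centroid_gt_x": round(r.centroid_gt.x_bar, 2),
        "centroid_pred_y": None if r.centroid_pred is None else round(r.centroid_pred.y_bar, 2),
        "centroid_pred_x": None if r.centroid_pred is None else round(r.centroid_pred.x_bar, 2),
        "distance_px": None if r.distance_px is None else round(r.distance_px, 2),
        "overlap_pct": round(r.overlap_pct, 2),
        "cropped_iou": round(r.cropped_iou, 2),
    }


def write_report(
    reports: list[tuple[str, LocalizationReport]],
    path: str | pathlib.Path,
) -> pd.DataFrame:
    """Write (sample_id, report) rows as CSV plus a JSON mirror.

    Values are stored at 2 decimal places; unmatched lesions serialize with
    explicit nulls in the predicted-centroid and distance fields. Returns
    the frame that was written. An empty list is refused.
    """
    if not reports:
        raise ValueError("refusing to write an empty report")
    path = pathlib.Path(path)
    rows = [_report_row(sid, r) for sid, r in reports]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(rows, indent=1))
    return frame


def read_report(path: str | pathlib.Path) -> pd.DataFrame:
    frame = pd.read_csv(pathlib.Path(path))
    return frame.where(pd.notna(frame), None)


def report_summary(frame: pd.DataFrame) -> dict:
    """Median/mean localization summary over matched lesions."""
    matched = frame[frame["distance_px"].notna()]
    n_matched = int(len(matched))
    return {
        "n_lesions": int(len(frame)),
        "n_matched": n_matched,
        "median_distance_px": (
            float(matched["distance_px"].median()) if n_matched else math.nan
        ),
        "mean_overlap_pct": (
            float(matched["overlap_pct"].mean()) if n_matched else 0.0
        ),
        "mean_cropped_iou": (
            float(matched["cropped_iou"].mean()) if n_matched else 0.0
        ),
    }
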