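"""Segmentation-overlap and centroid-localization metrics.

Implements the evaluation mathematics used throughout the package:

* Dice = (2|P∩G| + eps) / (|P| + |G| + eps) and IoU = |P∩G| / |P∪G|,
  related by the identity IoU = Dice / (2 − Dice) when computed from the
  same counts with eps = 0;
* mask centroids (mean 0-based pixel coordinate of the nonzero pixels),
  Euclidean centroid distance d, and the diagonal-normalized location match
  Overlap(%) = max(0, 100·(1 − d/D)) with D = sqrt(H² + W²);
* a cropped IoU restricted to the ground-truth lesion's bounding box plus a
  margin, which scores shape agreement near the lesion without penalizing
  distant background; and
* per-lesion reports that split the ground truth into 8-connected
  components and match each to a predicted component by one-to-one
  minimum-total-distance assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class Centroid:
    y_bar: float
    x_bar: float
    n_pixels: int


@dataclass
class LocalizationReport:
    """Per-lesion localization record (Table-style row).

    ``centroid_pred`` and ``distance_px`` are None for ground-truth lesions
    with no matching predicted component; such lesions score overlap 0 and
    cropped IoU 0.
    """

    lesion_id: int
    centroid_gt: Centroid
    centroid_pred: Centroid | None
    distance_px: float | None
    overlap_pct: float
    cropped_iou: float
    image_hw: tuple[int, int]

    @property
    def matched(self) -> bool:
        return self.centroid_pred is not None


def _check_pair(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P)
    G = np.asarray(G)
    if P.shape != G.shape:
        raise ValueError("mask shapes must match")
    return P > 0, G > 0


def dice_score(P: np.ndarray, G: np.ndarray, eps: float = 1e-5) -> float:
    P, G = _check_pair(P, G)
    inter = np.count_nonzero(P & G)
    return (2.0 * inter + eps) / (np.count_nonzero(P) + np.count_nonzero(G) + eps)


def iou(P: np.ndarray, G: np.ndarray) -> float:
    P, G = _check_pair(P, G)
    union = np.count_nonzero(P | G)
    if union == 0:
        return 1.0  # empty-agreement convention
    return np.count_nonzero(P & G) / union


def iou_from_dice(dice: float) -> float:
    """The standard Dice↔Jaccard conversion IoU = Dice / (2 − Dice)."""
    if not (0.0 <= dice <= 1.0):
        raise ValueError("dice must lie in [0, 1]")
    return dice / (2.0 - dice)


def mask_centroid(M: np.ndarray) -> Centroid:
    M = np.asarray(M) > 0
    ys, xs = np.nonzero(M)
    if ys.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    return Centroid(float(ys.mean()), float(xs.mean()), int(ys.size))


def centroid_distance(c_ref: Centroid, c_seg: Centroid) -> float:
    return math.hypot(c_ref.y_bar - c_seg.y_bar, c_ref.x_bar - c_seg.x_bar)


def overlap_percent(d: float, height: int, width: int) -> float:
    """Diagonal-normalized location match, clamped to [0, 100]."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    diag = math.hypot(height, width)
    return max(0.0, 100.0 * (1.0 - d / diag))


def _crop_box(G: np.ndarray, margin: int) -> tuple[slice, slice]:
    ys, xs = np.nonzero(G)
    h, w = G.shape
    return (
        slice(max(0, ys.min() - margin), min(h, ys.max() + margin + 1)),
        slice(max(0, xs.min() - margin), min(w, xs.max() + margin + 1)),
    )


def cropped_iou(P: np.ndarray, G: np.ndarray, margin: int = 10) -> float:
    """IoU inside the bounding box of G expanded by ``margin`` pixels."""
    P, G = _check_pair(P, G)
    if not G.any():
        raise ValueError("cropped_iou needs a nonempty ground-truth mask")
    box = _crop_box(G, margin)
    return iou(P[box], G[box])


def _components(M: np.ndarray) -> list[np.ndarray]:
    labels, n = ndimage.label(M, structure=EIGHT_CONNECTED)
    return [labels == k for k in range(1, n + 1)]


def per_lesion_reports(
    P: np.ndarray,
    G: np.ndarray,
    image_hw: tuple[int, int] | None = None,
    margin: int = 10,
) -> list[LocalizationReport]:
    """One localization report per ground-truth lesion.

    Ground-truth lesions are the 8-connected components of G. Predicted
    components are assigned one-to-one by minimizing the total centroid
    distance (optimal assignment; identical to exhaustive enumeration).
    Ground-truth lesions left without a partner are reported unmatched.
    The cropped IoU of a matched lesion compares the full prediction with
    that lesion inside its expanded bounding box.
    """
    P, G = _check_pair(P, G)
    if not G.any():
        raise ValueError("ground truth mask is empty")
    hw = image_hw if image_hw is not None else G.shape
    gt_comps = _components(G)
    pred_comps = _components(P)
    gt_cents = [mask_centroid(c) for c in gt_comps]
    pred_cents = [mask_centroid(c) for c in pred_comps]

    match: dict[int, int] = {}
    if pred_cents:
        cost = np.array(
            [[centroid_distance(g, p) for p in pred_cents] for g in gt_cents]
        )
        rows, cols = linear_sum_assignment(cost)
        match = dict(zip(rows, cols))

    reports = []
    for i, (comp, cg) in enumerate(zip(gt_comps, gt_cents)):
        if i in match:
            cp = pred_cents[match[i]]
            d = centroid_distance(cg, cp)
            ov = overlap_percent(d, hw[0], hw[1])
            ci = cropped_iou(P, comp, margin)
        else:
            cp, d, ov, ci = None, None, 0.0, 0.0
        reports.append(
            LocalizationReport(
                lesion_id=i,
                centroid_gt=cg,
                centroid_pred=cp,
                distance_px=d,
                overlap_pct=ov,
                cropped_iou=ci,
                image_hw=tuple(hw),
            )
        )
    return reports


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor resize of a binary mask (evaluation-size helper)."""
    from skimage.transform import resize

    out = resize(
        np.asarray(mask, dtype=float), (size, size), order=0,
        anti_aliasing=False, preserve_range=True,
    )
    return (out >= 0.5).astype(np.uint8)
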