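"""Sinogram construction and preprocessing.

A sinogram here is the parallel-beam Radon transform of a square image,
stored with rows = detector position t and columns = projection angle theta.
The acquisition geometry emulated throughout is the limited tomosynthesis
arc of -25..+25 degrees in 2.5 degree increments (21 projections).

Training examples pair the min-max normalized image sinogram with the
binarized sinogram of the lesion mask; a detector-row band around the lesion
trace can be extracted so the network sees a lesion-focused region.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import radon as _sk_radon
from skimage.transform import resize as _sk_resize

DEFAULT_ANGLE_RANGE = (-25.0, 25.0, 2.5)


@dataclass(frozen=True)
class AngleSet:
    """Strictly increasing projection angles in degrees."""

    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("AngleSet needs at least one angle")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.angles_deg)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles_deg, dtype=float)


def make_angle_set(min_deg: float, max_deg: float, step_deg: float) -> AngleSet:
    """Inclusive arithmetic angle sequence min, min+step, ..., max."""
    if step_deg <= 0:
        raise ValueError("step_deg must be > 0")
    if max_deg <= min_deg:
        raise ValueError("max_deg must exceed min_deg")
    span = max_deg - min_deg
    n = span / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError("(max - min) must be an integer multiple of step")
    n = int(round(n))
    return AngleSet(tuple(min_deg + step_deg * k for k in range(n + 1)))


def default_angle_set() -> AngleSet:
    """The ±25° / 2.5° limited-arc geometry (21 projections)."""
    return make_angle_set(*DEFAULT_ANGLE_RANGE)


@dataclass
class Sinogram:
    """Projection data: rows = detector position, columns = angle index."""

    data: np.ndarray
    angles: AngleSet
    source_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D")
        if self.data.shape[1] != len(self.angles):
            raise ValueError("column count must equal number of angles")

    @property
    def n_detectors(self) -> int:
        return self.data.shape[0]


@dataclass
class SinogramPair:
    """Co-registered image sinogram and binary mask sinogram.

    ``band`` records the detector-row interval (start, stop) a lesion-focused
    crop was taken from, and ``full_rows`` the detector count of the original
    uncropped sinogram, so predictions can be re-embedded before
    backprojection.
    """

    image_sino: Sinogram
    mask_sino: Sinogram
    sample_ref: dict
    band: tuple[int, int] | None = None
    full_rows: int | None = None

    def __post_init__(self) -> None:
        if self.image_sino.data.shape != self.mask_sino.data.shape:
            raise ValueError("image and mask sinograms must share shape")
        if self.image_sino.angles != self.mask_sino.angles:
            raise ValueError("image and mask sinograms must share angles")


def radon_transform(image: np.ndarray, angles: AngleSet) -> Sinogram:
    """Parallel-beam Radon transform of a square image.

    Detector positions span the image diagonal (no circular masking), so the
    sum of every column conserves the total image mass up to interpolation
    error. Column k is the projection at angles_deg[k].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square 2D; pad before calling")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    data = _sk_radon(image, theta=angles.as_array(), circle=False)
    return Sinogram(data=data, angles=angles, source_shape=image.shape)


def sinogram_pair(
    sample,
    angles: AngleSet | None = None,
    mask_threshold: float = 0.5,
) -> SinogramPair:
    """Build the (image sinogram, mask sinogram) training pair for a sample.

    The image sinogram is min-max normalized to [0, 1]. The mask sinogram is
    the Radon transform of the binary lesion mask, binarized at
    ``mask_threshold`` times its own maximum — a ray counts as crossing the
    lesion when its intersection length is at least that fraction of the
    longest chord. The default 0.5 keeps only the core trace, whose
    per-angle position encodes the lesion location; permissive thresholds
    produce wide bands that carry little positional information per angle.
    """
    if angles is None:
        angles = default_angle_set()
    if float(sample.image.max()) <= float(sample.image.min()):
        raise ValueError("constant image cannot be min-max normalized")
    img_s = radon_transform(sample.image, angles)
    lo, hi = float(img_s.data.min()), float(img_s.data.max())
    if hi <= lo:
        raise ValueError("constant image sinogram cannot be normalized")
    img_s.data = (img_s.data - lo) / (hi - lo)

    if np.any(sample.mask):
        mask_s = radon_transform(sample.mask.astype(np.float64), angles)
        mask_s.data = (mask_s.data >= mask_threshold * mask_s.data.max()).astype(
            np.float64
        )
    else:
        mask_s = Sinogram(
            data=np.zeros_like(img_s.data), angles=angles,
            source_shape=img_s.source_shape,
        )
    ref = {"patient_id": sample.patient_id, "modality": sample.modality}
    return SinogramPair(image_sino=img_s, mask_sino=mask_s, sample_ref=ref)


def extract_lesion_band(pair: SinogramPair, margin: int = 10) -> SinogramPair:
    """Crop both sinograms to the detector-row band of the lesion trace.

    The band is the minimal row interval containing every nonzero mask row,
    expanded by ``margin`` rows and clipped to the sinogram; the angle axis
    is untouched.
    """
    rows = np.flatnonzero(pair.mask_sino.data.any(axis=1))
    if rows.size == 0:
        raise ValueError(
            "mask sinogram is empty; use the full sinogram for inference"
        )
    full = pair.image_sino.n_detectors
    start = max(0, int(rows[0]) - margin)
    stop = min(full, int(rows[-1]) + margin + 1)
    img = replace(
        pair.image_sino, data=pair.image_sino.data[start:stop].copy()
    )
    msk = replace(
        pair.mask_sino, data=pair.mask_sino.data[start:stop].copy()
    )
    base = pair.band[0] if pair.band is not None else 0
    return SinogramPair(
        image_sino=img,
        mask_sino=msk,
        sample_ref=pair.sample_ref,
        band=(base + start, base + stop),
        full_rows=pair.full_rows if pair.full_rows is not None else full,
    )


def normalize_resize(sino: Sinogram | np.ndarray, target: int) -> np.ndarray:
    """Bilinear-resize to target x target, then min-max normalize to [0, 1].

    A constant input cannot be min-max scaled; it maps to all-zeros with a
    warning rather than an error.
    """
    if target < 16:
        raise ValueError("target size must be >= 16")
    data = sino.data if isinstance(sino, Sinogram) else np.asarray(sino, float)
    out = _sk_resize(
        data, (target, target), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    lo, hi = float(out.min()), float(out.max())
    if hi <= lo:
        warnings.warn("constant sinogram; normalize_resize returns zeros")
        return np.zeros((target, target), dtype=np.float64)
    return (out - lo) / (hi - lo)


def embed_band(
    grid: np.ndarray,
    band: tuple[int, int],
    full_rows: int,
    n_angles: int,
    binarize: bool = True,
) -> np.ndarray:
    """Map a model-sized band prediction back to full sinogram coordinates.

    Resizes ``grid`` (bilinear) to the original (band height, n_angles)
    window, optionally re-binarizes at 0.5, and pastes it into an otherwise
    zero full-height sinogram array.
    """
    start, stop = band
    win = _sk_resize(
        np.asarray(grid, float), (stop - start, n_angles), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    if binarize:
        win = (win >= 0.5).astype(np.float64)
    full = np.zeros((full_rows, n_angles), dtype=np.float64)
    full[start:stop] = win
    return full


# ---------------------------------------------------------------------------
# NPY + JSON sidecar persistence (rows = detector, cols = angle)

def save_sinogram(sino: Sinogram, stem: str | pathlib.Path,
                  suffix: str = "sino", normalized: bool = False) -> None:
    stem = pathlib.Path(stem)
    np.save(stem.with_suffix(f".{suffix}.npy"), sino.data)
    meta = {
        "angles_deg": list(sino.angles.angles_deg),
        "source_shape": list(sino.source_shape) if sino.source_shape else None,
        "normalized": normalized,
    }
    stem.with_suffix(f".{suffix}.json").write_text(json.dumps(meta))


def load_sinogram(stem: str | pathlib.Path, suffix: str = "sino") -> Sinogram:
    stem = pathlib.Path(stem)
    data = np.load(stem.with_suffix(f".{suffix}.npy"))
    meta = json.loads(stem.with_suffix(f".{suffix}.json").read_text())
    shape = tuple(meta["source_shape"]) if meta["source_shape"] else None
    return Sinogram(
        data=data, angles=AngleSet(tuple(meta["angles_deg"])), source_shape=shape
    )
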