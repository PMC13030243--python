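"""Seeded synthetic breast phantoms with annotated lesions.

Stands in for clinical mammography / DBT-slice inputs: an elliptical breast
support region filled with smooth low-frequency tissue texture, plus one or
more hyperintense elliptical lesions with optional boundary irregularity.
The DBT mode emulates the lower conspicuity of tomosynthesis slices by
scaling lesion/tissue contrast down and adding Gaussian noise.

Every sample is a pure function of its seed; datasets derive one RNG stream
per (seed, patient index, image index) so they are stable under reordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import pathlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

MAMMOGRAPHY = "mammography"
DBT = "dbt"
MODALITIES = (MAMMOGRAPHY, DBT)


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and intensity of one simulated mass.

    center_yx : (row, col) pixel coordinates of the lesion center.
    semi_axes : (a, b) ellipse semi-axes in pixels, both >= 2.
    rotation_deg : in-plane rotation of the ellipse.
    contrast : additive peak intensity in (0, 1]; masses are hyperintense.
    boundary_irregularity : amplitude (>= 0) of the radial harmonic
        perturbation applied to the ellipse boundary; 0 gives a pure ellipse.
    """

    center_yx: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0
    contrast: float = 0.3
    boundary_irregularity: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a < 2 or b < 2:
            raise ValueError("lesion semi-axes must both be >= 2 px")
        if not (0 < self.contrast <= 1):
            raise ValueError("lesion contrast must lie in (0, 1]")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")


@dataclass
class ImageSample:
    """A spatial-domain image with its binary lesion mask and provenance."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    modality: str
    lesions: list[LesionSpec] = field(default_factory=list)
    support: np.ndarray | None = None  # breast region; rebuilt as image > 0 if absent

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    def support_region(self) -> np.ndarray:
        if self.support is not None:
            return self.support
        return self.image > 0


@dataclass(frozen=True)
class PhantomDatasetConfig:
    """Dataset-level generation parameters.

    modality_mix is the fraction of DBT samples (default 0.2, roughly the
    272 / 1354 modality composition of the annotated clinical cohorts this
    generator emulates). dbt_contrast_scale <= 1 enforces that DBT lesions
    are never more conspicuous than mammography ones.
    """

    n_patients: int = 60
    images_per_patient: int = 2
    image_size: int = 256
    modality_mix: float = 0.2
    lesion_count_range: tuple[int, int] = (1, 2)
    dbt_noise_sigma: float = 0.03
    dbt_contrast_scale: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("need n_patients >= 3 for a 3-way patient split")
        if not (0 <= self.modality_mix <= 1):
            raise ValueError("modality_mix must lie in [0, 1]")
        if not (0 < self.dbt_contrast_scale <= 1):
            raise ValueError("dbt_contrast_scale must lie in (0, 1]")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid lesion_count_range")


def _phantom_from_rng(
    rng: np.random.Generator,
    size: int,
    modality: str,
    patient_id: str,
    dbt_noise_sigma: float,
    dbt_contrast_scale: float,
) -> ImageSample:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size * (0.5 + rng.uniform(-0.03, 0.03))
    cx = size * (0.5 + rng.uniform(-0.03, 0.03))
    a = size * rng.uniform(0.36, 0.44)  # area >= pi*0.36*0.31 ~ 35% of frame
    b = size * rng.uniform(0.31, 0.38)
    phi = rng.uniform(-0.25, 0.25)
    u = (yy - cy) * math.cos(phi) + (xx - cx) * math.sin(phi)
    v = -(yy - cy) * math.sin(phi) + (xx - cx) * math.cos(phi)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    support = rho2 <= 1.0

    # smooth parenchyma: dense core + band-limited gaussian random field
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 16.0)
    texture = texture / (texture.std() + 1e-12) * 0.05
    image = (0.35 + 0.25 * np.clip(1.0 - rho2, 0, None) + texture) * support

    if modality == DBT:
        inside = image[support]
        m = float(inside.mean()) if inside.size else 0.0
        image = np.where(support, m + dbt_contrast_scale * (image - m), 0.0)
        image = image + rng.normal(0.0, dbt_noise_sigma, image.shape)

    image = np.clip(image, 0.0, 1.0)
    return ImageSample(
        image=image,
        mask=np.zeros((size, size), dtype=np.uint8),
        patient_id=patient_id,
        modality=modality,
        lesions=[],
        support=support,
    )


def generate_phantom(
    size: int,
    modality: str = MAMMOGRAPHY,
    rng_seed: int | np.random.Generator = 0,
    *,
    patient_id: str = "P0000",
    dbt_noise_sigma: float = 0.03,
    dbt_contrast_scale: float = 0.6,
) -> ImageSample:
    """Generate a lesion-free breast phantom (all-zero mask).

    The breast support is an ellipse occupying >= 30% of the frame; inside it
    the tissue is a smooth dome plus low-frequency texture. DBT mode rescales
    contrast by ``dbt_contrast_scale`` and adds N(0, dbt_noise_sigma) noise.
    """
    if size < 64:
        raise ValueError("phantom size must be >= 64 px")
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return _phantom_from_rng(
        rng, size, modality, patient_id, dbt_noise_sigma, dbt_contrast_scale
    )


def _harmonic_phases(spec: LesionSpec, n: int) -> np.ndarray:
    """Deterministic pseudo-random phases derived from the spec fields."""
    key = json.dumps(
        [spec.center_yx, spec.semi_axes, spec.rotation_deg, spec.contrast,
         spec.boundary_irregularity],
        separators=(",", ":"),
    )
    digest = hashlib.blake2b(key.encode(), digest_size=8 * n).digest()
    ints = np.frombuffer(digest, dtype=np.uint64)
    return (ints / np.float64(2**64)) * 2 * np.pi


def lesion_footprint(spec: LesionSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one lesion: (binary footprint, smooth intensity bump).

    The boundary is the ellipse radius modulated by harmonics k=2..4 with
    deterministic phases (k=1 is excluded so the centroid stays on the
    specified center). The bump peaks at 1 in the center and falls smoothly
    to 0 at the (perturbed) boundary.
    """
    cy, cx = spec.center_yx
    a, b = spec.semi_axes
    th = math.radians(spec.rotation_deg)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    u = (yy - cy) * math.cos(th) + (xx - cx) * math.sin(th)
    v = -(yy - cy) * math.sin(th) + (xx - cx) * math.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    if spec.boundary_irregularity > 0:
        phi = np.arctan2(v, u)
        phases = _harmonic_phases(spec, 3)
        g = sum(np.cos(k * phi + phases[k - 2]) for k in (2, 3, 4)) / 3.0
        boundary = 1.0 + spec.boundary_irregularity * g
    else:
        boundary = np.ones_like(rho)

    inside = rho <= boundary
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(boundary > 0, rho / boundary, np.inf)
    bump = np.clip(1.0 - rel**2, 0.0, 1.0)
    return inside, bump


def add_lesion(sample: ImageSample, spec: LesionSpec) -> ImageSample:
    """Return a copy of ``sample`` with one more hyperintense lesion.

    Raises ValueError when the lesion center falls outside the breast support.
    """
    cy, cx = spec.center_yx
    iy, ix = int(round(cy)), int(round(cx))
    support = sample.support_region()
    h, w = support.shape
    if not (0 <= iy < h and 0 <= ix < w) or not support[iy, ix]:
        raise ValueError("lesion center lies outside the breast support region")

    inside, bump = lesion_footprint(spec, sample.image.shape)
    image = np.clip(sample.image + spec.contrast * bump, 0.0, 1.0)
    mask = sample.mask.copy()
    mask[inside] = 1
    return ImageSample(
        image=image,
        mask=mask,
        patient_id=sample.patient_id,
        modality=sample.modality,
        lesions=[*sample.lesions, spec],
        support=sample.support,
    )


def _place_lesions(
    sample: ImageSample, rng: np.random.Generator, n_lesions: int,
    contrast_scale: float,
) -> ImageSample:
    size = sample.image.shape[0]
    support = sample.support_region()
    # keep centers well inside the breast so the whole mass fits
    eroded = ndimage.binary_erosion(support, iterations=max(1, int(size * 0.08)))
    cand = np.argwhere(eroded)
    centers: list[tuple[float, float]] = []
    for _ in range(n_lesions):
        a = max(2.5, rng.uniform(0.025, 0.05) * size)
        b = max(2.0, a * rng.uniform(0.6, 1.0))
        for _attempt in range(100):
            cy, cx = cand[rng.integers(len(cand))]
            if all(math.hypot(cy - y0, cx - x0) > 4.5 * a for y0, x0 in centers):
                break
        else:
            continue  # crowded frame: silently place fewer lesions
        spec = LesionSpec(
            center_yx=(float(cy), float(cx)),
            semi_axes=(float(a), float(b)),
            rotation_deg=float(rng.uniform(0, 180)),
            contrast=float(rng.uniform(0.25, 0.45) * contrast_scale),
            boundary_irregularity=float(rng.uniform(0.0, 0.2)),
        )
        sample = add_lesion(sample, spec)
        centers.append((float(cy), float(cx)))
    return sample


def generate_dataset(config: PhantomDatasetConfig) -> list[ImageSample]:
    """Generate the full seeded dataset described by ``config``.

    Modality is assigned deterministically by global sample index so that a
    mix of m over N samples yields exactly round(m*N) DBT images, interleaved
    evenly; lesion counts are drawn uniformly from ``lesion_count_range``.
    """
    samples: list[ImageSample] = []
    i = 0
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        for j in range(config.images_per_patient):
            dbt_flag = math.floor((i + 1) * config.modality_mix) - math.floor(
                i * config.modality_mix
            ) >= 1
            modality = DBT if dbt_flag else MAMMOGRAPHY
            rng = np.random.default_rng([config.seed, p, j])
            sample = _phantom_from_rng(
                rng,
                config.image_size,
                modality,
                pid,
                config.dbt_noise_sigma,
                config.dbt_contrast_scale,
            )
            lo, hi = config.lesion_count_range
            n_lesions = int(rng.integers(lo, hi + 1))
            scale = config.dbt_contrast_scale if modality == DBT else 1.0
            sample = _place_lesions(sample, rng, n_lesions, scale)
            samples.append(sample)
            i += 1
    return samples


# ---------------------------------------------------------------------------
# dataset writer / reader (PNG images + PNG masks + one JSONL metadata file)

def save_dataset(samples: list[ImageSample], out_dir: str | pathlib.Path,
                 fmt: str = "png") -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "metadata.jsonl"
    with open(meta_path, "w") as fh:
        for k, s in enumerate(samples):
            stem = f"sample_{k:05d}"
            if fmt == "png":
                iio.imwrite(out / f"{stem}.png",
                            np.round(s.image * 255).astype(np.uint8))
            elif fmt == "npy":
                np.save(out / f"{stem}.npy", s.image.astype(np.float32))
            else:
                raise ValueError("fmt must be 'png' or 'npy'")
            iio.imwrite(out / f"{stem}.mask.png",
                        (s.mask.astype(np.uint8) * 255))
            record = {
                "stem": stem,
                "patient_id": s.patient_id,
                "modality": s.modality,
                "lesions": [dataclasses.asdict(sp) for sp in s.lesions],
            }
            fh.write(json.dumps(record) + "\n")


def load_dataset(in_dir: str | pathlib.Path) -> list[ImageSample]:
    src = pathlib.Path(in_dir)
    samples = []
    with open(src / "metadata.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            stem = rec["stem"]
            npy = src / f"{stem}.npy"
            if npy.exists():
                image = np.load(npy).astype(np.float64)
            else:
                image = iio.imread(src / f"{stem}.png").astype(np.float64) / 255.0
            mask = (iio.imread(src / f"{stem}.mask.png") > 0).astype(np.uint8)
            lesions = [
                LesionSpec(
                    center_yx=tuple(sp["center_yx"]),
                    semi_axes=tuple(sp["semi_axes"]),
                    rotation_deg=sp["rotation_deg"],
                    contrast=sp["contrast"],
                    boundary_irregularity=sp["boundary_irregularity"],
                )
                for sp in rec["lesions"]
            ]
            samples.append(
                ImageSample(image=image, mask=mask, patient_id=rec["patient_id"],
                            modality=rec["modality"], lesions=lesions)
            )
    return samples
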