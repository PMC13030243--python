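"""End-to-end orchestration: phantoms → sinograms → training → FBP → report.

A single master seed fans out to per-stage seeds by hashing the stage name,
so individual stages can be rerun in isolation and the full run is a pure
function of its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import fileio
from .metrics import per_lesion_reports, resize_mask
from .nn import UNetConfig, build_unet, predict_mask
from .phantoms import PhantomDatasetConfig, generate_dataset, save_dataset
from .reconstruction import reconstruct_mask
from .sinogram import (
    Sinogram,
    embed_band,
    extract_lesion_band,
    make_angle_set,
    normalize_resize,
    sinogram_pair,
)
from .training import TrainConfig, evaluate, patient_level_split, train


def stage_seed(master: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{stage}:{master}".encode()) ^ master) % (2**31)


@dataclass
class PipelineConfig:
    phantom: PhantomDatasetConfig = field(default_factory=PhantomDatasetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    angles: tuple[float, float, float] = (-25.0, 25.0, 2.5)
    radon_input: int = 256
    model_input: int = 128
    eval_image: int = 224
    crop_margin: int = 10
    base_channels: int = 32
    dropout_p: float = 0.2
    upsample_mode: str = "nearest"
    mask_threshold: float = 0.5
    recon_binarize: str = "rel_threshold"
    recon_rel: float = 0.5
    metrics_margin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_input % 16 != 0:
            raise ValueError("model_input must be divisible by 16")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        phantom = PhantomDatasetConfig(**raw.pop("phantom", {}))
        train_cfg = TrainConfig(**raw.pop("train", {}))
        if "angles" in raw:
            raw["angles"] = tuple(raw["angles"])
        return cls(phantom=phantom, train=train_cfg, **raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Example:
    """One training-ready pair plus what is needed to map back to space."""

    x: np.ndarray
    y: np.ndarray
    patient_id: str
    modality: str
    spatial_mask: np.ndarray
    band: tuple[int, int]
    full_rows: int
    n_angles: int
    source_shape: tuple[int, int]


def build_examples(samples, config: PipelineConfig) -> list[Example]:
    """Sinogram pairs with lesion-band crops, resized to the model input."""
    angles = make_angle_set(*config.angles)
    examples = []
    for s in samples:
        if not np.any(s.mask):
            continue
        pair = sinogram_pair(s, angles, mask_threshold=config.mask_threshold)
        full_rows = pair.image_sino.n_detectors
        band_pair = extract_lesion_band(pair, margin=config.crop_margin)
        x = normalize_resize(band_pair.image_sino, config.model_input)
        y_soft = normalize_resize(band_pair.mask_sino, config.model_input)
        y = (y_soft >= 0.5).astype(np.float64)
        examples.append(
            Example(
                x=x,
                y=y,
                patient_id=s.patient_id,
                modality=s.modality,
                spatial_mask=s.mask,
                band=band_pair.band,
                full_rows=full_rows,
                n_angles=len(angles),
                source_shape=pair.image_sino.source_shape,
            )
        )
    return examples


def localize_example(model, ex: Example, config: PipelineConfig):
    """Predict in the sinogram domain, backproject, report per lesion."""
    pred = predict_mask(model, ex.x)
    full = embed_band(pred, ex.band, ex.full_rows, ex.n_angles)
    sino = Sinogram(
        data=full,
        angles=make_angle_set(*config.angles),
        source_shape=ex.source_shape,
    )
    spatial_pred = reconstruct_mask(
        sino, binarize=config.recon_binarize, rel=config.recon_rel
    )
    size = config.eval_image
    pred_eval = resize_mask(spatial_pred, size)
    gt_eval = resize_mask(ex.spatial_mask, size)
    return per_lesion_reports(
        pred_eval, gt_eval, image_hw=(size, size), margin=config.metrics_margin
    )


def _filter_modality(samples, input_config: str):
    if input_config == "combined":
        return list(samples)
    return [s for s in samples if s.modality == input_config]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | pathlib.Path,
    force: bool = False,
) -> pathlib.Path:
    """Execute the full pipeline and persist every intermediate artifact.

    Refuses to reuse an existing non-empty run directory unless ``force``.
    Returns the run directory path.
    """
    out = pathlib.Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"run directory {out} exists; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kw) -> None:
        log_fh.write(json.dumps({"stage": stage, **kw}) + "\n")
        log_fh.flush()

    try:
        (out / "resolved_config.json").write_text(
            json.dumps(config.resolved(), indent=1)
        )
        log("config", seed=config.seed)

        phantom_cfg = dataclasses.replace(
            config.phantom,
            image_size=config.radon_input,
            seed=stage_seed(config.seed, "phantoms"),
        )
        samples = generate_dataset(phantom_cfg)
        save_dataset(samples, out / "phantoms")
        log("phantoms", n_samples=len(samples))

        samples = _filter_modality(samples, config.train.input_config)
        examples = build_examples(samples, config)
        log("sinograms", n_examples=len(examples))

        split_seed = stage_seed(config.seed, "split")
        train_set, val_set, test_set = patient_level_split(
            examples, config.train.split_fractions, seed=split_seed
        )
        if not train_set:
            raise RuntimeError("split produced an empty training set")
        log(
            "split",
            n_train=len(train_set),
            n_val=len(val_set),
            n_test=len(test_set),
        )

        unet_cfg = UNetConfig(
            base_channels=config.base_channels,
            dropout_p=config.dropout_p,
            upsample_mode=config.upsample_mode,
            input_size=config.model_input,
        )
        model = build_unet(unet_cfg, seed=stage_seed(config.seed, "init"))
        train_cfg = dataclasses.replace(
            config.train, seed=stage_seed(config.seed, "train")
        )
        pairs = lambda exs: [(e.x, e.y) for e in exs]  # noqa: E731
        model, history = train(
            model,
            pairs(train_set),
            pairs(val_set),
            train_cfg,
            log_fn=lambda rec: log("epoch", **rec),
        )
        model.save(out / "checkpoint.npz")
        history.to_frame().to_csv(out / "history.csv", index=False)
        log(
            "train",
            best_epoch=history.best_epoch,
            best_val_dice=history.best_val_dice,
        )

        sino_table = evaluate(model, pairs(test_set))
        sino_table.to_csv(out / "sinogram_metrics.csv", index=False)

        rows = []
        for k, ex in enumerate(test_set):
            for rep in localize_example(model, ex, config):
                rows.append((f"{ex.patient_id}_{k}", rep))
        frame = fileio.write_report(rows, out / "report.csv")
        summary = fileio.report_summary(frame)
        summary["test_mean_sino_dice"] = float(
            sino_table.loc[sino_table["sample"] == "mean", "dice"].iloc[0]
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        log("done", **summary)
    except Exception as exc:
        log("error", kind=type(exc).__name__, message=str(exc))
        raise
    finally:
        log_fh.close()
    return out
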