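"""Patient-level splitting, augmentation, and the optimization recipe.

Training minimizes the hybrid BCE+Dice objective with Adam (lr 1e-4, L2
weight decay 1e-6, batch size 16) over shuffled mini-batches; after each
epoch the validation Dice of the thresholded predictions is computed and
the weights with the highest validation Dice are retained. No learning-rate
schedule and no early stopping. Everything is reproducible from the config
seed — the numpy backend is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import dice_score, iou
from .nn import Adam, UNet, combined_loss, combined_loss_grad, predict_mask

INPUT_CONFIGS = ("mammography", "dbt", "combined")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-6
    batch_size: int = 16
    epochs: int = 100
    aug_rotation_deg: float = 15.0
    aug_hflip: bool = True
    aug_noise_sigma: float = 0.02
    aug_prob: float = 0.5
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0
    input_config: str = "combined"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9 or min(
            self.split_fractions
        ) <= 0:
            raise ValueError("split_fractions must be positive and sum to 1")
        if self.input_config not in INPUT_CONFIGS:
            raise ValueError(f"input_config must be one of {INPUT_CONFIGS}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int | None:
        if not self.val_dice:
            return None
        return int(np.argmax(self.val_dice))

    @property
    def best_val_dice(self) -> float | None:
        if not self.val_dice:
            return None
        return float(max(self.val_dice))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "train_dice": self.train_dice,
                "val_dice": self.val_dice,
            }
        )


def patient_level_split(samples: list, fractions=(0.7, 0.15, 0.15), seed: int = 0):
    """Partition samples into (train, val, test) with zero patient overlap.

    Patients — not images — are shuffled and partitioned, so all images of a
    patient (both modalities included) land in exactly one subset; every
    subset receives at least one patient.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
        raise ValueError("fractions must be positive and sum to 1")
    patients: list[str] = []
    for s in samples:
        pid = s.patient_id if hasattr(s, "patient_id") else s.sample_ref["patient_id"]
        if pid not in patients:
            patients.append(pid)
    if len(patients) < 3:
        raise ValueError("need >= 3 distinct patients for a 3-way split")
    order = list(np.random.default_rng(seed).permutation(len(patients)))
    shuffled = [patients[i] for i in order]
    n = len(patients)
    n_train = min(max(1, round(fractions[0] * n)), n - 2)
    n_val = min(max(1, round(fractions[1] * n)), n - n_train - 1)
    groups = (
        set(shuffled[:n_train]),
        set(shuffled[n_train : n_train + n_val]),
        set(shuffled[n_train + n_val :]),
    )

    def pid_of(s):
        return s.patient_id if hasattr(s, "patient_id") else s.sample_ref["patient_id"]

    return tuple([s for s in samples if pid_of(s) in g] for g in groups)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    rotation_deg: float = 15.0,
    hflip: bool = True,
    noise_sigma: float = 0.02,
    prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment one (image, mask) training grid pair.

    Each transform fires independently with probability ``prob``: a rotation
    uniform in ±rotation_deg applied identically to image and mask, a
    horizontal flip of both, and additive Gaussian noise on the image only.
    The mask is re-binarized after interpolation; the image is clipped back
    to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if rotation_deg > 0 and rng.random() < prob:
        angle = rng.uniform(-rotation_deg, rotation_deg)
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=1, mode="nearest")
    if hflip and rng.random() < prob:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if noise_sigma > 0 and rng.random() < prob:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return np.clip(image, 0.0, 1.0), (mask >= 0.5).astype(np.float64)


def _stack(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.asarray(x, dtype=np.float64) for x, _ in dataset])
    ys = np.stack([np.asarray(y, dtype=np.float64) for _, y in dataset])
    return xs, ys


def _mean_val_dice(model: UNet, dataset, chunk: int = 16) -> float:
    """Mean Dice of thresholded predictions, forwarded in batches."""
    scores = []
    for start in range(0, len(dataset), chunk):
        part = dataset[start : start + chunk]
        xs = np.stack([np.asarray(x, dtype=np.float64) for x, _ in part])
        probs = model.forward(xs[:, None], train=False)
        for (_, y), prob in zip(part, probs[:, 0]):
            scores.append(dice_score(prob >= 0.5, np.asarray(y) >= 0.5))
    return float(np.mean(scores))


def train(
    model: UNet,
    train_set,
    val_set,
    config: TrainConfig,
    log_fn=None,
) -> tuple[UNet, TrainHistory]:
    """Train ``model`` on (x, y) grid pairs; return best-validation weights.

    ``train_set`` / ``val_set`` are sequences of (image grid, binary mask
    grid) pairs at the model's input size. The checkpoint with the highest
    validation Dice (thresholded predictions, first argmax) is restored into
    the returned model. ``epochs=0`` returns the initial weights untouched.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    history = TrainHistory()
    if config.epochs == 0:
        return model, history

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    xs, ys = _stack(train_set)
    n = len(xs)
    best_weights = None
    best_dice = -np.inf

    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss, epoch_dice, n_batches = 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch_x = np.empty((len(idx), 1, *xs.shape[1:]), dtype=np.float64)
            batch_y = np.empty_like(batch_x)
            for k, i in enumerate(idx):
                xi, yi = augment(
                    xs[i], ys[i], rng,
                    rotation_deg=config.aug_rotation_deg,
                    hflip=config.aug_hflip,
                    noise_sigma=config.aug_noise_sigma,
                    prob=config.aug_prob,
                )
                batch_x[k, 0], batch_y[k, 0] = xi, yi
            pred = model.forward(batch_x, train=True).astype(np.float64)
            loss = combined_loss(pred, batch_y)
            if not np.isfinite(loss.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            model.zero_grad()
            model.backward(combined_loss_grad(pred, batch_y))
            opt.step()
            epoch_loss += loss.total
            epoch_dice += loss.dice_term
            n_batches += 1

        val_dice = _mean_val_dice(model, val_set)
        history.train_loss.append(epoch_loss / n_batches)
        history.train_dice.append(epoch_dice / n_batches)
        history.val_dice.append(val_dice)
        if val_dice > best_dice:
            best_dice = val_dice
            best_weights = model.get_weights()
        if log_fn is not None:
            log_fn(
                {
                    "epoch": epoch,
                    "train_loss": history.train_loss[-1],
                    "train_dice": history.train_dice[-1],
                    "val_dice": val_dice,
                }
            )

    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def evaluate(model: UNet, test_set) -> pd.DataFrame:
    """Per-sample and mean Dice/IoU of thresholded predictions.

    Returns a DataFrame with one row per test pair plus a trailing "mean"
    row; deterministic given the model and data.
    """
    if len(test_set) == 0:
        raise ValueError("test set must be non-empty")
    rows = []
    for k, (x, y) in enumerate(test_set):
        pred = predict_mask(model, x)
        gt = np.asarray(y) >= 0.5
        rows.append(
            {"sample": str(k), "dice": dice_score(pred, gt), "iou": iou(pred, gt)}
        )
    frame = pd.DataFrame(rows)
    mean_row = {
        "sample": "mean",
        "dice": frame["dice"].mean(),
        "iou": frame["iou"].mean(),
    }
    return pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
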