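"""Segmentation model: combined BCE + Dice loss, flip augmentation, seeded
training with Adam, and deterministic slice-by-slice inference.

The loss is ``L = L_BCE + L_DL`` with

    L_BCE = mean over pixels of -[y log(yhat) + (1 - y) log(1 - yhat)]
    L_DL  = 1 - (2 * sum(y*yhat) + 1) / (sum(y) + sum(yhat) + 1)

summed per sample (batch size 1), the combination suited to imbalanced
structures: BCE drives per-pixel calibration while the Dice term directly
rewards overlap of the small foreground.

Images enter the network normalised from Hounsfield units to [0, 1] through
a fixed [-1000, +1000] HU window, so the 100 HU calcification semantics
stay identical across exams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nn.unet import UNet2D, sigmoid

__all__ = [
    "TrainConfig",
    "ModelWeights",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "augment",
    "build_model",
    "build_and_train",
    "predict",
    "hu_to_unit",
]

EPS = 1e-7
HU_WINDOW = (-1000.0, 1000.0)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale settings (512x512 inputs, 24 base filters,
    depth-5 encoder, Adam at 1e-3, 200 epochs, dropout 0.5 on the descending
    path, flip augmentation).  ``desk()`` returns a small profile for CPU-scale
    experiments; it is a parameter preset, not a different code path.
    """

    input_resolution: int = 512
    base_filters: int = 24
    depth: int = 5
    batch_size: int = 1
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 200
    dropout_rate: float = 0.5
    augment_flips: bool = True
    lr_schedule: str = "constant"  # "constant" | "step" (x0.3 at 70% and 90% of epochs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.batch_size != 1:
            raise ValueError("per-sample optimisation only: batch_size must be 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "step"):
            raise ValueError(f"lr_schedule must be 'constant' or 'step', got {self.lr_schedule!r}")
        if self.depth < 2 or self.base_filters < 1:
            raise ValueError("depth must be >= 2 and base_filters >= 1")
        if self.input_resolution % 2 ** (self.depth - 1):
            raise ValueError(
                f"input_resolution {self.input_resolution} not divisible by 2**(depth-1)"
            )

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """64x64 / 8-base-filter / depth-3 profile, <=25 epochs, for CPU runs."""
        params = dict(
            input_resolution=64,
            base_filters=8,
            depth=3,
            epochs=25,
            dropout_rate=0.05,
            lr_schedule="step",
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ModelWeights:
    """Serialized parameter set tied to the config that produced it."""

    config: TrainConfig
    arrays: list[np.ndarray]
    history: pd.DataFrame | None = None

    @property
    def fingerprint(self) -> str:
        return self.config.fingerprint()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {f"p{i:03d}": a for i, a in enumerate(self.arrays)}
        payload["config_json"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)
        if self.history is not None:
            self.history.to_csv(path.with_suffix(".log.csv"), index=False)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ModelWeights":
        with np.load(path) as z:
            cfg = TrainConfig(**json.loads(bytes(z["config_json"]).decode()))
            keys = sorted(k for k in z.files if k.startswith("p"))
            arrays = [z[k] for k in keys]
        return cls(config=cfg, arrays=arrays)


# --- losses -----------------------------------------------------------------


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    return y, np.clip(yhat, EPS, 1.0 - EPS)


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions clipped to [eps, 1-eps]."""
    y, yh = _check_pair(y, yhat)
    return float(-(y * np.log(yh) + (1.0 - y) * np.log(1.0 - yh)).mean())


def dice_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Soft Dice loss 1 - (2*sum(y*yhat)+1) / (sum(y)+sum(yhat)+1).

    The +1 smoothing makes the empty/empty case a perfect score of 0.
    Sums run over all pixels of the sample; unclipped predictions are used
    (clipping only matters inside the logarithm of the BCE term).
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    return float(1.0 - (2.0 * (y * yhat).sum() + 1.0) / (y.sum() + yhat.sum() + 1.0))


def combined_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """L = L_BCE + L_DL, the exact sum of the two terms."""
    return bce_loss(y, yhat) + dice_loss(y, yhat)


def _loss_grad_wrt_logits(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d(L_BCE + L_DL)/dz for sigmoid output p = sigma(z).

    BCE through the sigmoid gives (p - y)/N exactly; for the Dice term,
    dL/dp_i = (A - 2 y_i B) / B^2 with A = 2*sum(y p)+1, B = sum(y)+sum(p)+1,
    chained with dp/dz = p(1-p).
    """
    y = y.astype(np.float64)
    p64 = p.astype(np.float64)
    n = y.size
    g_bce = (p64 - y) / n
    A = 2.0 * (y * p64).sum() + 1.0
    B = y.sum() + p64.sum() + 1.0
    g_dice = (A - 2.0 * y * B) / B**2 * (p64 * (1.0 - p64))
    return (g_bce + g_dice).astype(np.float32)


# --- data handling ----------------------------------------------------------


def hu_to_unit(img: np.ndarray) -> np.ndarray:
    """Fixed-window normalisation: [-1000, +1000] HU -> [0, 1]."""
    lo, hi = HU_WINDOW
    return np.clip((np.asarray(img, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator | int):
    """Apply the same horizontal/vertical flips to image and mask.

    Each axis is flipped independently with probability 0.5; flips preserve
    the mask pixel count and are involutions.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} must share geometry")
    img, msk = image, mask
    if rng.random() < 0.5:  # horizontal flip (left-right)
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:  # vertical flip (up-down)
        img, msk = img[::-1, :], msk[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# --- training / inference ---------------------------------------------------


def build_model(config: TrainConfig) -> UNet2D:
    return UNet2D(
        in_channels=1,
        base_filters=config.base_filters,
        depth=config.depth,
        dropout=config.dropout_rate,
        seed=config.seed,
    )


def build_and_train(
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    verbose: bool = False,
) -> ModelWeights:
    """Train the U-Net on (HU image, binary mask) pairs; fully seeded.

    Per-epoch mean total/BCE/Dice losses are recorded in ``history``.
    Raises on an empty training set or a non-finite loss (with the epoch in
    the message).
    """
    from .nn.layers import Adam

    pairs = list(train_set)
    if not pairs:
        raise ValueError("training set is empty")
    res = config.input_resolution
    for img, msk in pairs:
        if img.shape != (res, res) or msk.shape != (res, res):
            raise ValueError(
                f"training samples must be {(res, res)}, got image {img.shape} mask {msk.shape}"
            )
    model = build_model(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA46]))
    xs = [hu_to_unit(img) for img, _ in pairs]
    ys = [np.asarray(m, dtype=np.float32) for _, m in pairs]
    rows = []
    for epoch in range(config.epochs):
        if config.lr_schedule == "step":
            k = (epoch >= 0.7 * config.epochs) + (epoch >= 0.9 * config.epochs)
            opt.lr = config.learning_rate * 0.3**k
        order = rng.permutation(len(pairs))
        tot = np.zeros(3)
        for j in order:
            x, y = xs[j], ys[j]
            if config.augment_flips:
                x, y = augment(x, y, rng)
            p = model.forward(x, training=True)
            lb, ld = bce_loss(y, p), dice_loss(y, p)
            if not np.isfinite(lb + ld):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: BCE={lb}, Dice={ld}")
            tot += (lb + ld, lb, ld)
            opt.zero_grad()
            model.backward(_loss_grad_wrt_logits(y, p))
            opt.step()
        mean = tot / len(pairs)
        rows.append(dict(epoch=epoch, loss=mean[0], bce=mean[1], dice_loss=mean[2]))
        if verbose:
            print(f"epoch {epoch:3d}  L={mean[0]:.4f}  BCE={mean[1]:.4f}  DL={mean[2]:.4f}")
    return ModelWeights(config=config, arrays=model.get_weights(), history=pd.DataFrame(rows))


def predict(images: np.ndarray | Sequence[np.ndarray], weights: ModelWeights) -> np.ndarray:
    """Deterministic slice-by-slice inference.

    ``images`` is an (n, H, W) stack or a sequence of (H, W) HU images; the
    output probability stack preserves the input order regardless of any
    upstream shuffling, and repeated calls on identical input are identical
    (no dropout at inference).
    """
    imgs = np.asarray(images, dtype=np.float32)
    if imgs.ndim == 2:
        imgs = imgs[None]
    res = weights.config.input_resolution
    if imgs.shape[1:] != (res, res):
        raise ValueError(
            f"input slices are {imgs.shape[1:]}, model expects {(res, res)}; resample upstream"
        )
    model = build_model(weights.config)
    model.set_weights(weights.arrays)
    return np.stack([model.forward(hu_to_unit(img), training=False) for img in imgs])
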