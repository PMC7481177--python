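"""Convolutional denoising autoencoder (CDAE) pretraining.

The encoder compresses an L-sample window through three conv+ReLU+maxpool
stages; the decoder mirrors it with three upsample+conv stages back to L
samples.  Training minimizes mean-squared error between the reconstruction
of a noise-corrupted window and its clean original, so the encoder learns
pulse-shaped features that survive corruption — these three convolutional
layers are what gets transferred into the classifier trunk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .types import CANONICAL_NOISE_FACTORS, ValidationError


@dataclass(frozen=True)
class CdaeConfig:
    """Architecture + optimization settings.

    The learning-rate schedule is additive: when validation loss has not
    improved for ``lr_patience`` epochs, lr <- max(lr - lr_decrement,
    lr_floor).  Defaults: 200 epochs, patience 25, decrement 0.001.
    """

    input_length: int = 800
    enc_filters: tuple[int, int, int] = (32, 16, 8)
    dec_filters: tuple[int, int] = (16, 32)
    kernel: int = 5
    pool: int = 2
    lr: float = 1e-3
    lr_decrement: float = 1e-3
    lr_patience: int = 25
    lr_floor: float = 1e-5
    epochs: int = 200
    batch: int = 128
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.pool < 2:
            raise ValidationError("pool factor must be >= 2")
        if self.input_length % self.pool ** 3:
            raise ValidationError(
                f"input_length {self.input_length} must be divisible by "
                f"pool^3 = {self.pool ** 3}")
        if self.latent_length >= self.input_length:
            raise ValidationError(
                "latent_length must be smaller than input_length")

    @property
    def latent_length(self) -> int:
        """Temporal length of the latent map after three pooling stages."""
        return self.input_length // self.pool ** 3


@dataclass
class EncoderWeights:
    """The three encoder conv layers' parameters, in order."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or len(self.biases) != 3:
            raise ValidationError("encoder transfer needs exactly 3 conv layers")

    def save(self, path: Path | str) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Path | str) -> "EncoderWeights":
        data = nn.load_npz(path)
        return cls(weights=[data[f"W{i}"] for i in range(3)],
                   biases=[data[f"b{i}"] for i in range(3)])


class Cdae:
    """Encoder/decoder pair with shared persistence helpers."""

    def __init__(self, config: CdaeConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, p = config.kernel, config.pool
        f1, f2, f3 = config.enc_filters
        d1, d2 = config.dec_filters
        self.encoder = nn.Sequential([
            nn.Conv1D(1, f1, k, rng, "enc1", input_grad=False), nn.ReLU(),
            nn.MaxPool1D(p),
            nn.Conv1D(f1, f2, k, rng, "enc2"), nn.ReLU(), nn.MaxPool1D(p),
            nn.Conv1D(f2, f3, k, rng, "enc3"), nn.ReLU(), nn.MaxPool1D(p),
        ])
        self.decoder = nn.Sequential([
            nn.Upsample1D(p), nn.Conv1D(f3, d1, k, rng, "dec1"), nn.ReLU(),
            nn.Upsample1D(p), nn.Conv1D(d1, d2, k, rng, "dec2"), nn.ReLU(),
            nn.Upsample1D(p), nn.Conv1D(d2, 1, k, rng, "dec3"),
        ])

    @property
    def params(self) -> list[nn.Param]:
        return self.encoder.params + self.decoder.params

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        y = self.encoder.forward(x, training=training, rng=rng)
        return self.decoder.forward(y, training=training, rng=rng)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(grad))

    def encode(self, windows: np.ndarray) -> np.ndarray:
        """Latent feature maps, shape (n, latent_length, enc_filters[-1])."""
        return self.encoder.forward(np.asarray(windows)[:, :, None],
                                    training=False)

    def save(self, path: Path | str) -> None:
        arrays = {f"encoder.{k}": v for k, v in self.encoder.state_arrays().items()}
        arrays.update({f"decoder.{k}": v
                       for k, v in self.decoder.state_arrays().items()})
        nn.save_npz(path, arrays, config=self.config.__dict__ | {
            "enc_filters": list(self.config.enc_filters),
            "dec_filters": list(self.config.dec_filters)})

    @classmethod
    def load(cls, path: Path | str, config: CdaeConfig) -> "Cdae":
        model = cls(config)
        data = nn.load_npz(path)
        model.encoder.load_state_arrays(
            {k[len("encoder."):]: v for k, v in data.items()
             if k.startswith("encoder.")})
        model.decoder.load_state_arrays(
            {k[len("decoder."):]: v for k, v in data.items()
             if k.startswith("decoder.")})
        return model


def build_cdae(config: CdaeConfig | None = None) -> Cdae:
    """Construct a seed-deterministic, He-initialized CDAE."""
    return Cdae(config or CdaeConfig())


def corrupt_batch(clean: np.ndarray, factors=CANONICAL_NOISE_FACTORS,
                  rng: np.random.Generator | None = None,
                  assignment: str = "round_robin",
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each clean window a noise factor and add Gaussian noise.

    Noise sd per item = factor * sd(clean item).  Returns (corrupted,
    assigned factors); the clean/corrupted pairing is row-wise.
    """
    factors = np.asarray(sorted(factors), dtype=float)
    if factors.size == 0:
        raise ValidationError("factor set must be non-empty")
    if np.any(factors < 0):
        raise ValidationError("noise factors must be >= 0")
    rng = rng or np.random.default_rng(0)
    clean = np.asarray(clean, dtype=float)
    n = clean.shape[0]
    if assignment == "round_robin":
        assigned = factors[np.arange(n) % len(factors)]
    elif assignment == "random":
        assigned = rng.choice(factors, size=n)
    else:
        raise ValidationError(f"unknown assignment '{assignment}'")
    sd = clean.std(axis=1, keepdims=True)
    noise = rng.normal(size=clean.shape) * sd * assigned[:, None]
    return clean + noise, assigned


def mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((np.asarray(a) - np.asarray(b)) ** 2))


def train_cdae(model: Cdae, corrupted: np.ndarray, clean: np.ndarray,
               config: CdaeConfig | None = None, verbose: bool = False,
               ) -> dict[str, list[float]]:
    """Train on (corrupted -> clean) pairs with MSE loss and Adam.

    A ``val_fraction`` tail of the data (by record order) is held out for
    the learning-rate schedule.  Returns per-epoch train/val loss history
    and the learning-rate trace.
    """
    config = config or model.config
    corrupted = np.asarray(corrupted, dtype=float)
    clean = np.asarray(clean, dtype=float)
    if corrupted.shape != clean.shape or corrupted.ndim != 2:
        raise ValidationError("corrupted and clean must be equal-shape 2-D arrays")
    if corrupted.shape[0] == 0:
        raise ValidationError("dataset must be non-empty")
    n_val = max(1, int(round(config.val_fraction * corrupted.shape[0])))
    xc_tr, xc_val = corrupted[:-n_val], corrupted[-n_val:]
    xt_tr, xt_val = clean[:-n_val], clean[-n_val:]
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params, lr=config.lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    stall = 0
    n = xc_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch):
            idx = order[start:start + config.batch]
            xb = xc_tr[idx][:, :, None]
            tb = xt_tr[idx][:, :, None]
            z = model.forward(xb, training=True, rng=rng)
            diff = z - tb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            opt.zero_grad()
            model.backward(2.0 * diff / diff.size)
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss = mse(reconstruct(model, xc_val), xt_val)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr = max(opt.lr - config.lr_decrement, config.lr_floor)
                stall = 0
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs} "
                  f"train={history['train_loss'][-1]:.5f} val={val_loss:.5f} "
                  f"lr={opt.lr:.5f}")
    return history


def reconstruct(model: Cdae, corrupted: np.ndarray, batch: int = 256) -> np.ndarray:
    """Denoise windows; accepts (L,) or (n, L), returns the same shape."""
    x = np.asarray(corrupted, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.config.input_length:
        raise ValidationError(
            f"expected input length {model.config.input_length}, got {x.shape[1]}")
    out = []
    for start in range(0, len(x), batch):
        z = model.forward(x[start:start + batch][:, :, None], training=False)
        out.append(z[:, :, 0])
    z = np.concatenate(out, axis=0)
    return z[0] if single else z


def extract_encoder(model: Cdae) -> EncoderWeights:
    """Copy out the three encoder conv layers for transfer."""
    convs = [layer for layer in model.encoder.layers
             if isinstance(layer, nn.Conv1D)]
    return EncoderWeights(weights=[c.W.value.copy() for c in convs],
                          biases=[c.b.value.copy() for c in convs])
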