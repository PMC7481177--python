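"""Multitask PPG classifier: shared convolutional trunk, a 3-way signal
quality arm and a 2-way rhythm (AF vs non-AF) arm.

The trunk has six hidden convolutional layers.  Layers 1-3 mirror the CDAE
encoder exactly (conv+ReLU+maxpool) so pretrained encoder weights drop in
unchanged; layers 4-6 are conv + leaky-ReLU + batch norm + dropout.  Four
ablation variants are supported: multitask/single-task crossed with
pretrained/random trunk initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from . import nn
from .cdae import EncoderWeights
from .types import PredictionRecord, ValidationError


class Variant(Enum):
    MT_PRETRAINED = "MT_PRETRAINED"
    MT_RANDOM = "MT_RANDOM"
    ST_PRETRAINED = "ST_PRETRAINED"
    ST_RANDOM = "ST_RANDOM"

    @property
    def multitask(self) -> bool:
        return self in (Variant.MT_PRETRAINED, Variant.MT_RANDOM)

    @property
    def pretrained(self) -> bool:
        return self in (Variant.MT_PRETRAINED, Variant.ST_PRETRAINED)


@dataclass(frozen=True)
class TrunkConfig:
    enc_filters: tuple[int, int, int] = (32, 16, 8)
    enc_kernel: int = 5
    pool: int = 2
    deep_filters: tuple[int, int, int] = (32, 32, 32)
    deep_kernel: int = 3
    dropout: float = 0.25
    leaky_alpha: float = 0.1


@dataclass(frozen=True)
class QaArmConfig:
    conv_filters: int = 32
    kernel: int = 3
    dropout: float = 0.25
    dense: int = 64
    classes: int = 3


@dataclass(frozen=True)
class EventArmConfig:
    conv_filters: tuple[int, int, int] = (32, 32, 32)
    kernel: int = 3
    dropout: float = 0.25
    dense: int = 64
    classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """Joint loss = w_af * CE(rhythm) + w_qa * CE(quality)."""

    w_af: float = 1.0
    w_qa: float = 1.0
    epochs: int = 10
    batch: int = 64
    lr: float = 1e-3
    seed: int = 0
    class_weighting: bool = True
    #: cyclic warm restarts: a fresh Adam state (and shuffle stream) each
    #: epoch, which acts as an implicit step-size anneal late in training
    warm_restarts: bool = False
    #: relative learning rate applied to transferred encoder layers during
    #: fine-tuning (discriminative fine-tuning; 1.0 = uniform)
    transferred_lr_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.w_af < 0 or self.w_qa < 0:
            raise ValidationError("loss weights must be >= 0")
        if self.transferred_lr_scale < 0:
            raise ValidationError("transferred_lr_scale must be >= 0")


def _build_trunk(cfg: TrunkConfig, rng: np.random.Generator) -> nn.Sequential:
    k, p = cfg.enc_kernel, cfg.pool
    f1, f2, f3 = cfg.enc_filters
    layers: list[nn.Layer] = [
        nn.Conv1D(1, f1, k, rng, "trunk1", input_grad=False), nn.ReLU(),
        nn.MaxPool1D(p),
        nn.Conv1D(f1, f2, k, rng, "trunk2"), nn.ReLU(), nn.MaxPool1D(p),
        nn.Conv1D(f2, f3, k, rng, "trunk3"), nn.ReLU(), nn.MaxPool1D(p),
    ]
    in_ch = f3
    for i, filt in enumerate(cfg.deep_filters):
        layers += [
            nn.Conv1D(in_ch, filt, cfg.deep_kernel, rng, f"trunk{4 + i}"),
            nn.LeakyReLU(cfg.leaky_alpha),
            nn.BatchNorm(filt, name=f"trunk{4 + i}.bn"),
            nn.Dropout(cfg.dropout),
        ]
        in_ch = filt
    return nn.Sequential(layers)

#: Number of layer objects making up trunk hidden layers 1-3 (the encoder
#: block): 3 x (conv, relu, pool).  Used for activation probes and transfer.
ENCODER_BLOCK_LEN = 9


def _build_qa_arm(cfg: QaArmConfig, in_ch: int, latent_len: int,
                  rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Conv1D(in_ch, cfg.conv_filters, cfg.kernel, rng, "qa.conv"),
        nn.ReLU(),
        nn.BatchNorm(cfg.conv_filters, name="qa.bn"),
        nn.Dropout(cfg.dropout),
        nn.Flatten(),
        nn.Dense(latent_len * cfg.conv_filters, cfg.dense, rng, "qa.fc1"),
        nn.ReLU(),
        nn.Dense(cfg.dense, cfg.classes, rng, "qa.fc2"),
    ])


def _build_event_arm(cfg: EventArmConfig, in_ch: int, latent_len: int,
                     rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch = in_ch
    for i, filt in enumerate(cfg.conv_filters):
        layers += [
            nn.Conv1D(ch, filt, cfg.kernel, rng, f"af.conv{i + 1}"),
            nn.ReLU(),
            nn.BatchNorm(filt, name=f"af.bn{i + 1}"),
            nn.Dropout(cfg.dropout),
        ]
        ch = filt
    layers += [
        nn.Flatten(),
        nn.Dense(latent_len * ch, cfg.dense, rng, "af.fc1"),
        nn.ReLU(),
        nn.Dense(cfg.dense, cfg.classes, rng, "af.fc2"),
    ]
    return nn.Sequential(layers)


class DeepBeatModel:
    """Shared trunk + task arms; see module docstring."""

    def __init__(self, variant: Variant = Variant.MT_PRETRAINED,
                 input_length: int = 800,
                 trunk: TrunkConfig | None = None,
                 qa_arm: QaArmConfig | None = None,
                 event_arm: EventArmConfig | None = None,
                 seed: int = 0) -> None:
        self.variant = variant
        self.input_length = input_length
        self.trunk_cfg = trunk or TrunkConfig()
        self.qa_cfg = qa_arm or QaArmConfig()
        self.event_cfg = event_arm or EventArmConfig()
        self.seed = seed
        if input_length % self.trunk_cfg.pool ** 3:
            raise ValidationError(
                f"input_length {input_length} not divisible by "
                f"pool^3 = {self.trunk_cfg.pool ** 3}")
        self.latent_len = input_length // self.trunk_cfg.pool ** 3
        rng = np.random.default_rng(seed)
        self.trunk = _build_trunk(self.trunk_cfg, rng)
        trunk_out_ch = self.trunk_cfg.deep_filters[-1]
        # event arm drawn before the optional QA arm so single-task and
        # multitask builds from the same seed share trunk + event weights
        self.event_head = _build_event_arm(self.event_cfg, trunk_out_ch,
                                           self.latent_len, rng)
        self.qa_head = (_build_qa_arm(self.qa_cfg, trunk_out_ch,
                                      self.latent_len, rng)
                        if variant.multitask else None)
        self._transferred = False
        self._transferred_params: list[nn.Param] = []

    # ------------------------------------------------------------------
    @property
    def params(self) -> list[nn.Param]:
        ps = self.trunk.params + self.event_head.params
        if self.qa_head is not None:
            ps += self.qa_head.params
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                ) -> tuple[np.ndarray, np.ndarray | None]:
        """Returns (af_logits, qa_logits or None). ``x`` is (n, L) or (n, L, 1)."""
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.input_length:
            raise ValidationError(
                f"expected windows of length {self.input_length}, got {x.shape[1]}")
        h = self.trunk.forward(x, training=training, rng=rng)
        af = self.event_head.forward(h, training=training, rng=rng)
        qa = (self.qa_head.forward(h, training=training, rng=rng)
              if self.qa_head is not None else None)
        return af, qa

    def encoder_activations(self, x: np.ndarray) -> np.ndarray:
        """Activations after trunk hidden layer 3 (the transferred block)."""
        if x.ndim == 2:
            x = x[:, :, None]
        return self.trunk.forward_upto(x, ENCODER_BLOCK_LEN, training=False)

    # ------------------------------------------------------------------
    def transfer_encoder_weights(self, enc: EncoderWeights) -> "DeepBeatModel":
        """Copy pretrained encoder parameters into trunk layers 1-3.

        Layers stay trainable (full fine-tuning).  Idempotent.
        """
        if not self.variant.pretrained:
            raise ValidationError(
                f"variant {self.variant.value} uses random initialization; "
                "encoder transfer is not part of its pipeline")
        convs = [l for l in self.trunk.layers[:ENCODER_BLOCK_LEN]
                 if isinstance(l, nn.Conv1D)]
        for conv, w, b in zip(convs, enc.weights, enc.biases):
            if conv.W.value.shape != w.shape or conv.b.value.shape != b.shape:
                raise ValidationError(
                    f"encoder shape mismatch: trunk expects "
                    f"{conv.W.value.shape}/{conv.b.value.shape}, got "
                    f"{w.shape}/{b.shape}")
            conv.W.value = w.copy()
            conv.b.value = b.copy()
            conv.W.grad = np.zeros_like(conv.W.value)
            conv.b.grad = np.zeros_like(conv.b.value)
        self._transferred = True
        self._transferred_params = [p for c in convs for p in (c.W, c.b)]
        return self

    # ------------------------------------------------------------------
    def predict(self, windows: np.ndarray, batch: int = 256,
                window_ids: list[str] | None = None,
                subject_ids: list[str] | None = None,
                ) -> list[PredictionRecord]:
        """Deterministic inference (dropout off, batch norm in running mode)."""
        X = np.asarray(windows, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        records = []
        for start in range(0, len(X), batch):
            af_logits, qa_logits = self.forward(X[start:start + batch],
                                                training=False)
            af_p = nn.softmax(af_logits)
            qa_p = nn.softmax(qa_logits) if qa_logits is not None else None
            for i in range(af_p.shape[0]):
                j = start + i
                records.append(PredictionRecord(
                    window_id=(window_ids[j] if window_ids else f"w{j:06d}"),
                    af_probs=af_p[i],
                    qa_probs=None if qa_p is None else qa_p[i],
                    subject_id=(subject_ids[j] if subject_ids else ""),
                ))
        return records

    def predict_proba(self, windows: np.ndarray, batch: int = 256,
                      ) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(windows, dtype=float)
        af_all, qa_all = [], []
        for start in range(0, len(X), batch):
            af_logits, qa_logits = self.forward(X[start:start + batch],
                                                training=False)
            af_all.append(nn.softmax(af_logits))
            if qa_logits is not None:
                qa_all.append(nn.softmax(qa_logits))
        return (np.concatenate(af_all),
                np.concatenate(qa_all) if qa_all else None)

    def embed(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        """Embedding vectors: the last dense activations before the rhythm
        prediction layer (width = event arm dense size)."""
        X = np.asarray(windows, dtype=float)
        stop = len(self.event_head.layers) - 1  # up to the ReLU after fc1
        out = []
        for start in range(0, len(X), batch):
            xb = X[start:start + batch]
            h = self.trunk.forward(xb[:, :, None], training=False)
            out.append(self.event_head.forward_upto(h, stop, training=False))
        return np.concatenate(out, axis=0)

    # -- persistence ----------------------------------------------------
    def _blocks(self) -> dict[str, nn.Sequential]:
        blocks = {"trunk": self.trunk, "event": self.event_head}
        if self.qa_head is not None:
            blocks["qa"] = self.qa_head
        return blocks

    def save(self, path: Path | str) -> None:
        arrays = {}
        for prefix, block in self._blocks().items():
            arrays.update({f"{prefix}.{k}": v
                           for k, v in block.state_arrays().items()})
        nn.save_npz(path, arrays, config={
            "variant": self.variant.value,
            "input_length": self.input_length,
            "seed": self.seed,
        })

    def load(self, path: Path | str) -> "DeepBeatModel":
        data = nn.load_npz(path)
        for prefix, block in self._blocks().items():
            block.load_state_arrays(
                {k[len(prefix) + 1:]: v for k, v in data.items()
                 if k.startswith(prefix + ".")})
        return self

    def get_state(self) -> dict[str, np.ndarray]:
        arrays = {}
        for prefix, block in self._blocks().items():
            arrays.update({f"{prefix}.{k}": v.copy()
                           for k, v in block.state_arrays().items()})
        return arrays

    def set_state(self, arrays: dict[str, np.ndarray]) -> None:
        for prefix, block in self._blocks().items():
            block.load_state_arrays(
                {k[len(prefix) + 1:]: v for k, v in arrays.items()
                 if k.startswith(prefix + ".")})


def build_deepbeat(variant: Variant = Variant.MT_PRETRAINED,
                   input_length: int = 800,
                   trunk: TrunkConfig | None = None,
                   qa_arm: QaArmConfig | None = None,
                   event_arm: EventArmConfig | None = None,
                   seed: int = 0) -> DeepBeatModel:
    return DeepBeatModel(variant=variant, input_length=input_length,
                         trunk=trunk, qa_arm=qa_arm, event_arm=event_arm,
                         seed=seed)


def build_qa_standalone(input_length: int = 800, seed: int = 0) -> nn.Sequential:
    """Trunk layers 1-3 + the QA arm as one standalone quality classifier
    (used for label propagation from a scored subset)."""
    rng = np.random.default_rng(seed)
    tcfg = TrunkConfig()
    k, p = tcfg.enc_kernel, tcfg.pool
    f1, f2, f3 = tcfg.enc_filters
    latent_len = input_length // p ** 3
    trunk_layers: list[nn.Layer] = [
        nn.Conv1D(1, f1, k, rng, "qs1"), nn.ReLU(), nn.MaxPool1D(p),
        nn.Conv1D(f1, f2, k, rng, "qs2"), nn.ReLU(), nn.MaxPool1D(p),
        nn.Conv1D(f2, f3, k, rng, "qs3"), nn.ReLU(), nn.MaxPool1D(p),
    ]
    arm = _build_qa_arm(QaArmConfig(), f3, latent_len, rng)
    return nn.Sequential(trunk_layers + arm.layers)


def _class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(y, minlength=n_classes)
    return counts.sum() / (n_classes * np.maximum(counts, 1.0))


def _weighted_macro_f1(y_true: np.ndarray, y_pred: np.ndarray,
                       classes: list[int]) -> float:
    # local import keeps evaluate as the single metrics authority
    from .evaluate import confusion, metrics_from_counts, weighted_macro

    counts = confusion(list(y_true), list(y_pred), classes)
    per_class = metrics_from_counts(counts)
    report = weighted_macro(per_class,
                            {c: int(np.sum(y_true == c)) for c in classes})
    return report.aggregate["f1"]


def train(model: DeepBeatModel, X_train: np.ndarray, y_af: np.ndarray,
          y_qa: np.ndarray | None, X_val: np.ndarray, yv_af: np.ndarray,
          yv_qa: np.ndarray | None, cfg: TrainConfig | None = None,
          verbose: bool = False) -> dict[str, list[float]]:
    """Train with joint cross-entropy; keep the checkpoint with the best
    validation weighted-macro F1 on the rhythm task.

    Single-task variants (or ``w_qa == 0``) ignore the quality labels.
    """
    cfg = cfg or TrainConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_af = np.asarray(y_af, dtype=int)
    if len(np.unique(y_af)) < 2:
        raise ValidationError("training rhythm labels contain a single class")
    use_qa = model.qa_head is not None and cfg.w_qa > 0
    if use_qa:
        if y_qa is None:
            raise ValidationError("multitask training requires quality labels")
        y_qa = np.asarray(y_qa, dtype=int)
    if model.variant.multitask and cfg.w_qa <= 0 and verbose:
        print("note: multitask graph trained with w_qa=0 (single-task loss)")
    rng = np.random.default_rng(cfg.seed + 7)
    opt = nn.Adam(model.params, lr=cfg.lr)
    af_w = _class_weights(y_af, 2) if cfg.class_weighting else np.ones(2)
    qa_w = (_class_weights(y_qa, 3) if (use_qa and cfg.class_weighting)
            else np.ones(3))
    transferred = (model._transferred_params
                   if cfg.transferred_lr_scale != 1.0 else [])
    history: dict[str, list[float]] = {"af_loss": [], "qa_loss": [], "val_f1": []}
    best_f1, best_state = -1.0, model.get_state()
    n = len(X_train)
    for epoch in range(cfg.epochs):
        if cfg.warm_restarts:
            rng = np.random.default_rng(cfg.seed + 1000 * epoch + 7)
            opt = nn.Adam(model.params, lr=cfg.lr)
        order = rng.permutation(n)
        af_sum = qa_sum = 0.0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            xb = X_train[idx][:, :, None]
            h = model.trunk.forward(xb, training=True, rng=rng)
            af_logits = model.event_head.forward(h, training=True, rng=rng)
            af_loss, af_grad = nn.softmax_xent(af_logits, y_af[idx],
                                               af_w[y_af[idx]])
            grad_h = model.event_head.backward(cfg.w_af * af_grad)
            qa_loss = 0.0
            if use_qa:
                qa_logits = model.qa_head.forward(h, training=True, rng=rng)
                qa_loss, qa_grad = nn.softmax_xent(qa_logits, y_qa[idx],
                                                   qa_w[y_qa[idx]])
                grad_h = grad_h + model.qa_head.backward(cfg.w_qa * qa_grad)
            if not np.isfinite(af_loss) or not np.isfinite(qa_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.trunk.backward(grad_h)
            for p in transferred:
                p.grad *= cfg.transferred_lr_scale
            opt.step()
            af_sum += af_loss * len(idx)
            qa_sum += qa_loss * len(idx)
        af_probs, _ = model.predict_proba(X_val)
        val_f1 = _weighted_macro_f1(np.asarray(yv_af, dtype=int),
                                    af_probs.argmax(axis=1), [0, 1])
        history["af_loss"].append(af_sum / n)
        history["qa_loss"].append(qa_sum / n)
        history["val_f1"].append(val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = model.get_state()
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} af={af_sum / n:.4f} "
                  f"qa={qa_sum / n:.4f} val_f1={val_f1:.4f}")
    model.set_state(best_state)
    return history
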