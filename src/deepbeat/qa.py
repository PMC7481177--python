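"""Three-class signal-quality assessment (excellent / acceptable / poor).

Three label sources are provided:

* :func:`qa_oracle` — ground truth for simulated records, a pure function
  of the Gaussian noise factor.
* :func:`rule_based_sqi` — a deterministic waveform-feature scorer
  (skewness, plausible peak count, peak-prominence consistency, clipping),
  a minimal stand-in for published PPG quality criteria.
* :func:`propagate_labels` — trains a small convolutional classifier (the
  classifier's QA arm, standalone) on a scored subset and labels the rest,
  mirroring label propagation from a small expert-scored pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from . import nn
from .simulator import qa_from_noise_factor
from .types import QaClass, SignalWindow, SimulatedRecord, ValidationError

QA_CLASSES = (QaClass.POOR, QaClass.ACCEPTABLE, QaClass.EXCELLENT)


def qa_oracle(record: SimulatedRecord) -> QaClass:
    """Ground-truth quality of a simulated record (noise-factor thresholds)."""
    return qa_from_noise_factor(record.noise_factor)


@dataclass(frozen=True)
class SqiFeatures:
    skewness: float
    peak_count: int
    peak_prominence_cv: float
    clipping_fraction: float


def sqi_features(samples: np.ndarray, fs_eff: float) -> SqiFeatures:
    """Waveform features behind the rule-based quality score.

    Peaks are detected with a refractory distance of one 220-bpm interval
    and a minimum prominence of 0.2 of the standardized range, so pure
    noise yields wildly inconsistent prominences while clean pulses are
    regular.
    """
    x = np.asarray(samples, dtype=float)
    skew = float(stats.skew(x)) if x.std() > 0 else 0.0
    min_dist = max(1, int(round(60.0 / 220.0 * fs_eff)))
    peaks, props = sps.find_peaks(x, distance=min_dist, prominence=0.2)
    prom = props.get("prominences", np.array([]))
    if len(prom) >= 2 and prom.mean() > 0:
        prom_cv = float(prom.std() / prom.mean())
    elif len(prom) == 1:
        prom_cv = 0.0
    else:
        prom_cv = float("inf")
    clip = float(np.mean((x <= 1e-3) | (x >= 1.0 - 1e-3)))
    return SqiFeatures(skewness=skew, peak_count=int(len(peaks)),
                       peak_prominence_cv=prom_cv, clipping_fraction=clip)


#: Plausible peak counts for 30-220 bpm over a 25-s window.
PEAKS_MIN, PEAKS_MAX = 12, 92

#: Skewness bounds: PPG pulses point up, so a usable window is clearly
#: right-skewed; symmetric windows are noise-dominated.
SKEW_POOR, SKEW_EXCELLENT = 0.2, 0.6


def rule_based_sqi(window: SignalWindow) -> QaClass:
    """Deterministic quality class from :func:`sqi_features`.

    Excellent requires strongly right-skewed samples (pulses point up), a
    plausible peak count, consistent prominences and negligible clipping;
    poor means no detectable pulse structure (near-symmetric amplitude
    distribution, implausible peak count or wildly inconsistent
    prominences) or heavy clipping; everything else is acceptable.
    """
    f = sqi_features(window.samples, window.fs_eff)
    structure_ok = PEAKS_MIN <= f.peak_count <= PEAKS_MAX
    if (not structure_ok or f.clipping_fraction > 0.10
            or not np.isfinite(f.peak_prominence_cv)
            or f.peak_prominence_cv > 0.9 or f.skewness < SKEW_POOR):
        return QaClass.POOR
    if (f.skewness > SKEW_EXCELLENT and f.peak_prominence_cv < 0.5
            and f.clipping_fraction < 0.01):
        return QaClass.EXCELLENT
    return QaClass.ACCEPTABLE


def _qa_to_index(label: QaClass) -> int:
    return {QaClass.POOR: 0, QaClass.ACCEPTABLE: 1, QaClass.EXCELLENT: 2}[label]


def _index_to_qa(idx: int) -> QaClass:
    return QA_CLASSES[idx]


def propagate_labels(scored_windows: np.ndarray, scored_labels: list[QaClass],
                     unscored_windows: np.ndarray, seed: int = 0,
                     epochs: int = 12, batch: int = 64,
                     ) -> tuple[list[QaClass], np.ndarray]:
    """Label unscored windows from a small scored pool.

    Trains the quality arm of the classifier architecture, standalone, on
    the scored windows (all three classes must be present), then predicts a
    class and a confidence (max softmax probability) for every unscored
    window.
    """
    from .model import build_qa_standalone  # lazy: avoids import cycle

    y = np.array([_qa_to_index(l) for l in scored_labels])
    present = set(y.tolist())
    if present != {0, 1, 2}:
        missing = [QA_CLASSES[i].name for i in sorted({0, 1, 2} - present)]
        raise ValidationError(
            f"scored subset must contain all three quality classes; "
            f"missing {missing}")
    X = np.asarray(scored_windows, dtype=float)
    net = build_qa_standalone(input_length=X.shape[1], seed=seed)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(net.params, lr=1e-3)
    # inverse-frequency class weights
    counts = np.bincount(y, minlength=3)
    cls_w = counts.sum() / (3.0 * np.maximum(counts, 1))
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb = X[idx][:, :, None]
            logits = net.forward(xb, training=True, rng=rng)
            loss, grad = nn.softmax_xent(logits, y[idx], cls_w[y[idx]])
            if not np.isfinite(loss):
                raise RuntimeError("non-finite loss during label propagation")
            opt.zero_grad()
            net.backward(grad)
            opt.step()
    probs = _predict_probs(net, np.asarray(unscored_windows, dtype=float))
    labels = [_index_to_qa(int(i)) for i in probs.argmax(axis=1)]
    return labels, probs.max(axis=1)


def _predict_probs(net: nn.Sequential, X: np.ndarray, batch: int = 256) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch):
        logits = net.forward(X[start:start + batch][:, :, None], training=False)
        out.append(nn.softmax(logits))
    return np.concatenate(out, axis=0)


def ordinal_score(label: QaClass) -> int:
    """POOR=0 < ACCEPTABLE=1 < EXCELLENT=2, for monotonicity checks."""
    return _qa_to_index(label)
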