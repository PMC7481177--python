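"""Raw PPG -> model-ready windows.

Fixed pipeline order: bandpass filter -> downsample by 4 -> cut windows ->
per-window min-max standardization to [0, 1].  Filtering happens before the
per-window standardization so slow drift never dominates the window range.
Heterogeneous input rates are first resampled to 128 Hz so a 25-s window is
always L = 800 samples at 32 Hz effective rate.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .types import (
    DEFAULT_FS,
    QaClass,
    Rhythm,
    SignalWindow,
    ValidationError,
    WindowSpec,
)

logger = logging.getLogger(__name__)

#: Bandpass corners in Hz: covers 30-220 bpm fundamentals plus harmonics.
DEFAULT_BAND = (0.5, 8.0)


def bandpass(x: np.ndarray, fs: float, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass (applied forward-backward)."""
    if not 0 < low < high < fs / 2:
        raise ValidationError(
            f"require 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased decimation; output length = floor(len(x)/factor)."""
    if factor < 1 or int(factor) != factor:
        raise ValidationError(f"factor must be a positive integer, got {factor}")
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    out = sps.decimate(x, int(factor), zero_phase=True)
    return out[: len(x) // int(factor)]


def resample_to(x: np.ndarray, fs_in: float, fs_out: float = DEFAULT_FS) -> np.ndarray:
    """Polyphase resampling so all sources share the 128 Hz device rate."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValidationError("sampling rates must be positive")
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float),
                             frac.numerator, frac.denominator)


def standardize(window: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; a constant window maps to all zeros."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValidationError("window must be non-empty")
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        return np.zeros_like(w)
    return (w - lo) / (hi - lo)


def window_signal(x: np.ndarray, spec: WindowSpec,
                  rhythm: Rhythm = Rhythm.UNKNOWN,
                  qa: QaClass = QaClass.UNKNOWN,
                  subject_id: str = "") -> list[SignalWindow]:
    """Full pipeline on one trace sampled at ``spec.fs_in``.

    Windows start at multiples of the stride; a trailing partial window is
    discarded.  A trace shorter than one window yields an empty list and a
    warning.
    """
    x = np.asarray(x, dtype=float)
    filtered = bandpass(x, spec.fs_in)
    down = downsample(filtered, spec.downsample_factor)
    fs_eff = spec.fs_eff
    length = spec.length
    step = int(round(spec.effective_stride * fs_eff))
    if len(down) < length:
        logger.warning(
            "signal too short for one window (%d < %d samples); returning none",
            len(down), length)
        return []
    windows = []
    idx = 0
    for start in range(0, len(down) - length + 1, step):
        seg = standardize(down[start:start + length])
        win = SignalWindow(samples=seg, fs_eff=fs_eff, rhythm=rhythm, qa=qa,
                           subject_id=subject_id, window_index=idx)
        win.validate()
        windows.append(win)
        idx += 1
    return windows


def windows_to_matrix(windows: list[SignalWindow]) -> np.ndarray:
    """Stack windows into an (n, L) float matrix."""
    if not windows:
        raise ValidationError("no windows to stack")
    return np.stack([w.samples for w in windows])
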