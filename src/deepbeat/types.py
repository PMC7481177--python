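"""Shared domain types: rhythms, quality classes, simulation specs, windows."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Canonical Gaussian corruption factors used for simulation and CDAE input.
CANONICAL_NOISE_FACTORS: tuple[float, ...] = (0.001, 0.25, 0.5, 0.75, 1.0, 2.0, 5.0)

#: Default device sampling rate (Hz).
DEFAULT_FS = 128.0

#: Default window length in seconds.
DEFAULT_WINDOW_SECONDS = 25.0

#: Default downsampling factor applied during preprocessing.
DEFAULT_DOWNSAMPLE = 4

#: Model input length in samples at the defaults: 25 s x 128 Hz / 4.
DEFAULT_INPUT_LENGTH = int(DEFAULT_WINDOW_SECONDS * DEFAULT_FS / DEFAULT_DOWNSAMPLE)


class Rhythm(Enum):
    SINUS = "SINUS"
    AF = "AF"
    UNKNOWN = "UNKNOWN"


class QaClass(Enum):
    """Three-level signal quality, ordered EXCELLENT > ACCEPTABLE > POOR.

    'Poor' and 'noise' are treated as synonyms for the lowest class.
    """

    EXCELLENT = 2
    ACCEPTABLE = 1
    POOR = 0
    UNKNOWN = -1


class ValidationError(ValueError):
    """Raised when a spec or input violates a documented invariant."""


@dataclass(frozen=True)
class BeatTrainSpec:
    """Beat-timing specification for one simulated record.

    ``rr_variability`` is the coefficient of variation of beat-to-beat
    intervals: small for sinus rhythm, large for the irregularly irregular
    timing of atrial fibrillation.
    """

    rhythm: Rhythm
    mean_hr: float = 75.0
    duration: float = 25.0
    rr_variability: float = 0.05

    def __post_init__(self) -> None:
        if self.rhythm not in (Rhythm.SINUS, Rhythm.AF):
            raise ValidationError(f"rhythm must be SINUS or AF, got {self.rhythm}")
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValidationError(f"mean_hr must be in [30, 220], got {self.mean_hr}")
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.rr_variability < 0:
            raise ValidationError(
                f"rr_variability must be >= 0, got {self.rr_variability}")
        if self.rhythm is Rhythm.SINUS and self.rr_variability > 0.1:
            raise ValidationError(
                f"rr_variability for SINUS must be <= 0.1, got {self.rr_variability}")
        if self.rhythm is Rhythm.AF and self.rr_variability < 0.15:
            raise ValidationError(
                f"rr_variability for AF must be >= 0.15, got {self.rr_variability}")


@dataclass(frozen=True)
class ModulationSpec:
    """Respiratory-band modulation: additive baseline wander plus
    multiplicative amplitude modulation."""

    bw_freq: float = 0.25
    bw_amp: float = 0.3
    am_freq: float = 0.2
    am_depth: float = 0.2

    def __post_init__(self) -> None:
        for name, f in (("bw_freq", self.bw_freq), ("am_freq", self.am_freq)):
            if not 0 < f <= 1:
                raise ValidationError(f"{name} must be in (0, 1] Hz, got {f}")
        if self.bw_amp < 0:
            raise ValidationError(f"bw_amp must be >= 0, got {self.bw_amp}")
        if not 0 <= self.am_depth < 1:
            raise ValidationError(f"am_depth must be in [0, 1), got {self.am_depth}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian corruption scaled by the per-signal std."""

    noise_factor: float

    def __post_init__(self) -> None:
        if self.noise_factor < 0:
            raise ValidationError(
                f"noise_factor must be >= 0, got {self.noise_factor}")


@dataclass
class SimulatedRecord:
    """A paired clean/corrupted synthetic PPG trace with ground truth."""

    clean: np.ndarray
    corrupted: np.ndarray
    fs: float
    rhythm: Rhythm
    noise_factor: float
    qa_true: QaClass
    seed: int
    record_id: str = ""

    def __post_init__(self) -> None:
        if len(self.clean) != len(self.corrupted):
            raise ValidationError("clean and corrupted must have equal length")


@dataclass(frozen=True)
class WindowSpec:
    """Windowing parameters for preprocessing.

    At the defaults (t=25 s, fs_in=128 Hz, downsample 4) a window is
    L = 800 samples at 32 Hz effective rate.
    """

    t: float = DEFAULT_WINDOW_SECONDS
    fs_in: float = DEFAULT_FS
    downsample_factor: int = DEFAULT_DOWNSAMPLE
    stride: float | None = None  # None -> non-overlapping (stride = t)

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValidationError(f"t must be > 0, got {self.t}")
        if self.downsample_factor < 1 or int(self.downsample_factor) != self.downsample_factor:
            raise ValidationError(
                f"downsample_factor must be a positive integer, got "
                f"{self.downsample_factor}")
        raw = self.fs_in * self.t / self.downsample_factor
        if abs(raw - round(raw)) > 1e-9:
            raise ValidationError(
                f"fs_in*t/downsample_factor must be integer, got {raw}")
        s = self.effective_stride
        if not 0 < s <= self.t:
            raise ValidationError(f"stride must be in (0, t], got {s}")

    @property
    def effective_stride(self) -> float:
        return self.t if self.stride is None else self.stride

    @property
    def length(self) -> int:
        """Window length L in samples after downsampling."""
        return round(self.fs_in * self.t / self.downsample_factor)

    @property
    def fs_eff(self) -> float:
        return self.fs_in / self.downsample_factor


@dataclass
class SignalWindow:
    """A fixed-length, [0,1]-standardized model input window."""

    samples: np.ndarray
    fs_eff: float
    rhythm: Rhythm = Rhythm.UNKNOWN
    qa: QaClass = QaClass.UNKNOWN
    subject_id: str = ""
    window_index: int = 0

    def validate(self) -> None:
        s = self.samples
        if not np.all(np.isfinite(s)):
            raise ValidationError("window contains non-finite samples")
        lo, hi = float(s.min()), float(s.max())
        degenerate = lo == hi == 0.0
        if not degenerate and not (abs(lo) < 1e-12 and abs(hi - 1.0) < 1e-12):
            raise ValidationError(
                f"window not standardized to [0, 1]: min={lo}, max={hi}")


@dataclass
class PredictionRecord:
    """Per-window softmax outputs for the QA (3-way) and AF (2-way) heads."""

    window_id: str
    af_probs: np.ndarray
    qa_probs: np.ndarray | None = None
    subject_id: str = ""

    @property
    def af_pred(self) -> int:
        return int(np.argmax(self.af_probs))

    @property
    def qa_pred(self) -> int | None:
        if self.qa_probs is None:
            return None
        return int(np.argmax(self.qa_probs))


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-stage seed fan-out: hash of (label, global seed), < 2^31."""
    import hashlib

    h = hashlib.sha256(f"{label}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)
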