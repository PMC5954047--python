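"""Per-trial signal conditioning: mean removal, band-pass, Hilbert envelope.

All operations act on epoched data, one trial at a time (or vectorized
over trials along the last-but-one axis); there is no cross-trial
padding or state. The band-pass is a zero-phase (forward-backward)
Butterworth, the envelope is the magnitude of the analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dataio import ValidationError


@dataclass(frozen=True)
class BandPassSpec:
    """Band edges (Hz), sampling rate (Hz) and Butterworth order."""

    fmin: float
    fmax: float
    fs: float
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.fmin < self.fmax:
            raise ValidationError(f"need 0 < fmin < fmax, got ({self.fmin}, {self.fmax})")
        if self.fmax >= self.fs / 2:
            raise ValidationError(
                f"fmax={self.fmax} must be below the Nyquist frequency {self.fs / 2}"
            )
        if self.order < 2 or self.order % 2:
            raise ValidationError("order must be an even positive integer")


def remove_channel_means(trial: np.ndarray, *, spatial: bool = False) -> np.ndarray:
    """Subtract each channel's temporal mean from an (M, C) trial.

    With ``spatial=True`` the common average reference (mean over
    channels at each sample) is subtracted instead; the temporal variant
    is the default DC-removal step of the pipeline.
    """
    trial = np.asarray(trial, dtype=np.float64)
    if not np.isfinite(trial).all():
        raise ValidationError("non-finite input")
    axis = -1 if spatial else -2
    return trial - trial.mean(axis=axis, keepdims=True)


def _sos(spec: BandPassSpec) -> np.ndarray:
    return signal.butter(
        spec.order, (spec.fmin, spec.fmax), btype="bandpass", fs=spec.fs, output="sos"
    )


def bandpass(x: np.ndarray, spec: BandPassSpec, *, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis`` (no group delay)."""
    x = np.asarray(x, dtype=np.float64)
    m = x.shape[axis]
    if m <= 3 * spec.order:
        raise ValidationError(
            f"signal length {m} too short for an order-{spec.order} zero-phase filter"
        )
    return signal.sosfiltfilt(_sos(spec), x, axis=axis)


def hilbert_envelope(x: np.ndarray, *, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude), >= |x|."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[axis] < 2:
        raise ValidationError("need at least 2 samples")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite input")
    return np.abs(signal.hilbert(x, axis=axis))
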