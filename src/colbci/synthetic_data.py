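"""Two-class motor-imagery-like EEG with known ground truth.

Every trial is pink (1/f) background noise on all channels; each
informative channel additionally carries a random-phase oscillation at a
frequency drawn inside that channel's designated mu/beta-range band. The
class effect is on amplitude, mimicking event-related
(de)synchronization: the oscillation amplitude is base * (1 + effect)
for class-1 trials and base * (1 - effect) for class-0 trials.
Uninformative channels are pure noise, so their class distributions are
identical. Channels are generated independently (no volume-conduction
mixing by default); classes are balanced and the whole dataset is a
deterministic function of the seed.

Defaults emulate a desk-scale version of the public benchmark layout
(a hundred-plus channels, 100-140 trials per class, 100 Hz, few-second
epochs): 32 channels, 200 trials, 3 s at 100 Hz, 5 informative channels
with bands inside 8-30 Hz, effect 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import EpochsSet, ValidationError

#: informative-channel bands (Hz) used by default, all inside the mu/beta range
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (8.54, 12.71),
    (10.42, 12.71),
    (12.71, 15.51),
    (18.92, 23.08),
    (23.08, 28.16),
)
DEFAULT_INFORMATIVE: tuple[int, ...] = (2, 7, 13, 21, 28)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the package's standard study conditions."""

    n_trials: int = 200
    n_channels: int = 32
    fs: float = 100.0
    duration: float = 3.0
    informative_channels: tuple[int, ...] = DEFAULT_INFORMATIVE
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    effect: float = 0.8
    osc_amplitude: float = 0.4
    noise_sd: float = 1.0
    pink_exponent: float = 1.0
    mixing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2 or self.n_channels < 1:
            raise ValidationError("need at least 2 trials and 1 channel")
        if self.effect < 0:
            raise ValidationError("effect size must be nonnegative")
        if len(self.bands) != len(self.informative_channels):
            raise ValidationError("need one band per informative channel")
        for ch in self.informative_channels:
            if not 0 <= ch < self.n_channels:
                raise ValidationError(f"informative channel {ch} out of range")
        for lo, hi in self.bands:
            if not 0 < lo < hi < self.fs / 2:
                raise ValidationError(f"band ({lo}, {hi}) outside (0, Nyquist)")
        if self.noise_sd <= 0 or self.duration <= 0 or self.fs <= 0:
            raise ValidationError("noise_sd, duration and fs must be positive")


@dataclass
class SyntheticGroundTruth:
    """What the generator actually planted, per channel and per trial."""

    spec: SyntheticSpec
    labels: np.ndarray
    channel_bands: list[tuple[float, float] | None] = field(default_factory=list)

    @property
    def informative_channels(self) -> np.ndarray:
        return np.asarray(self.spec.informative_channels)


def make_spec(
    n_trials: int = 200,
    n_channels: int = 32,
    effect: float = 0.8,
    seed: int = 0,
    **kwargs,
) -> SyntheticSpec:
    """Spec with informative channels spread over an arbitrary channel count.

    Plants min(5, max(1, C // 6)) informative channels, evenly spaced,
    cycling through the default mu/beta bands.
    """
    k = min(len(DEFAULT_BANDS), max(1, n_channels // 6))
    step = n_channels / (k + 1)
    channels = tuple(int(round(step * (i + 1))) for i in range(k))
    bands = tuple(DEFAULT_BANDS[i % len(DEFAULT_BANDS)] for i in range(k))
    return SyntheticSpec(
        n_trials=n_trials,
        n_channels=n_channels,
        effect=effect,
        seed=seed,
        informative_channels=channels,
        bands=bands,
        **kwargs,
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC component
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_mi_dataset(spec: SyntheticSpec) -> tuple[EpochsSet, SyntheticGroundTruth]:
    """Simulate a labeled two-class dataset; bit-identical for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_trials, spec.n_channels
    m = int(round(spec.duration * spec.fs))
    t = np.arange(m) / spec.fs

    labels = np.zeros(n, dtype=np.int64)
    labels[n // 2 :] = 1
    rng.shuffle(labels)

    data = spec.noise_sd * _pink_noise(rng, (n, c, m), spec.pink_exponent)

    amp_by_class = (
        spec.osc_amplitude * (1.0 - spec.effect),
        spec.osc_amplitude * (1.0 + spec.effect),
    )
    channel_bands: list[tuple[float, float] | None] = [None] * c
    for ch, (lo, hi) in zip(spec.informative_channels, spec.bands):
        channel_bands[ch] = (lo, hi)
        freq = rng.uniform(lo, hi, size=n)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
        amps = np.where(labels == 1, amp_by_class[1], amp_by_class[0])
        data[:, ch, :] += amps[:, None] * np.sin(
            2.0 * np.pi * freq[:, None] * t[None, :] + phase[:, None]
        )

    if spec.mixing > 0:
        mix = np.eye(c) + spec.mixing * rng.standard_normal((c, c)) / np.sqrt(c)
        data = np.einsum("dc,ncm->ndm", mix, data)

    epochs = EpochsSet(
        data=np.moveaxis(data, 1, 2),  # -> (N, M, C)
        fs=spec.fs,
        labels=labels,
        channel_names=[f"sim{j:02d}" for j in range(c)],
    )
    return epochs, SyntheticGroundTruth(spec=spec, labels=labels, channel_bands=channel_bands)
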