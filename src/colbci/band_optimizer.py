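"""Channel-specific optimal frequency band (OFB) search.

For each channel, candidate (fmin, fmax) pairs are drawn from the
geometric grid {f0 * theta**k, k = 0..Nf} and scored by the Fisher
criterion of the log-envelope-power feature

    gamma = log( (1/M) * ||envelope||^2 ),

computed on band-pass filtered, mean-removed trials. The pair with the
highest F-score is the channel's OFB.

Two enumeration modes exist. ``fidelity`` walks exactly the printed
grid-search loops — the initial pair (0, 1) followed by
nfmin = 1..Nf-1, nfmax = nfmin..Nf — which enumerates 45 candidates for
Nf = 9, eight of them zero-width; a zero-width band cannot be filtered
and is assigned score -inf. ``full`` scans every pair with
nfmin < nfmax over the whole grid (also 45 pairs for Nf = 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ChannelBandSpec, ValidationError
from .preprocess import BandPassSpec, bandpass, hilbert_envelope

#: variance-sum floor in the F-score denominator, guards degenerate features
FSCORE_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class FrequencyGrid:
    """Geometric frequency grid values[k] = f0 * theta**k, k = 0..n_f."""

    f0: float
    theta: float
    n_f: int
    values: tuple[float, ...]


def frequency_grid(f0: float, theta: float, n_f: int) -> FrequencyGrid:
    if f0 <= 0 or theta <= 1 or n_f < 1:
        raise ValidationError("need f0 > 0, theta > 1, n_f >= 1")
    values = tuple(f0 * theta**k for k in range(n_f + 1))
    return FrequencyGrid(f0=f0, theta=theta, n_f=n_f, values=values)


def candidate_bands(grid: FrequencyGrid, mode: str = "fidelity") -> list[tuple[int, int]]:
    """Enumerate candidate (nfmin, nfmax) index pairs in loop order.

    ``fidelity`` may include degenerate pairs with nfmin == nfmax; they
    count as enumerated candidates but are skipped during scoring.
    """
    nf = grid.n_f
    if mode == "fidelity":
        pairs = [(0, 1)]
        for lo in range(1, nf):
            for hi in range(lo, nf + 1):
                pairs.append((lo, hi))
        return pairs
    if mode == "full":
        return [(lo, hi) for lo in range(nf + 1) for hi in range(lo + 1, nf + 1)]
    raise ValidationError(f"unknown band search mode {mode!r}")


def log_power_feature(envelope: np.ndarray, *, axis: int = -1) -> np.ndarray:
    """gamma = log of the mean squared envelope along ``axis``."""
    envelope = np.asarray(envelope, dtype=np.float64)
    power = np.mean(np.square(envelope), axis=axis)
    if np.any(power <= 0):
        raise ValidationError("all-zero envelope: log-power feature undefined")
    return np.log(power)


def f_score(gamma_pos: np.ndarray, gamma_neg: np.ndarray) -> float:
    """Fisher criterion: squared mean difference over summed population variances."""
    gamma_pos = np.asarray(gamma_pos, dtype=np.float64)
    gamma_neg = np.asarray(gamma_neg, dtype=np.float64)
    if gamma_pos.size == 0 or gamma_neg.size == 0:
        raise ValidationError("both classes must be non-empty")
    num = (gamma_pos.mean() - gamma_neg.mean()) ** 2
    den = gamma_pos.var() + gamma_neg.var()
    return float(num / max(den, FSCORE_VAR_FLOOR))


def band_feature_table(
    channel_data: np.ndarray,
    fs: float,
    grid: FrequencyGrid,
    mode: str = "fidelity",
    order: int = 4,
) -> dict[tuple[int, int], np.ndarray]:
    """Features of every trial at every scorable candidate band of one channel.

    ``channel_data`` is (N, M), already mean-removed. Returns a dict
    mapping non-degenerate (nfmin, nfmax) pairs to length-N feature
    vectors; features do not depend on labels, so the table can be
    shared across cross-validation folds.
    """
    channel_data = np.asarray(channel_data, dtype=np.float64)
    table: dict[tuple[int, int], np.ndarray] = {}
    for lo, hi in candidate_bands(grid, mode):
        if lo == hi or (lo, hi) in table:
            continue
        spec = BandPassSpec(grid.values[lo], grid.values[hi], fs, order)
        filtered = bandpass(channel_data, spec, axis=-1)
        table[(lo, hi)] = log_power_feature(hilbert_envelope(filtered, axis=-1), axis=-1)
    return table


def select_band(
    channel_data: np.ndarray,
    labels: np.ndarray,
    channel: int,
    fs: float,
    grid: FrequencyGrid,
    mode: str = "fidelity",
    order: int = 4,
    feature_table: dict[tuple[int, int], np.ndarray] | None = None,
) -> ChannelBandSpec:
    """Best-scoring candidate band of one channel (grid search).

    Ties are broken by loop order: a later candidate replaces the
    incumbent only on a strict F-score improvement. ``feature_table``
    may carry precomputed features (restricted to the training trials).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("band selection requires both classes")
    if grid.values[-1] >= fs / 2:
        raise ValidationError(
            f"grid top {grid.values[-1]:.2f} Hz reaches the Nyquist frequency {fs / 2}"
        )
    if feature_table is None:
        feature_table = band_feature_table(channel_data, fs, grid, mode, order)
    pos = labels == 1
    best_pair: tuple[int, int] | None = None
    best_score = -np.inf
    for pair in candidate_bands(grid, mode):
        if pair[0] == pair[1]:
            continue  # zero-width band: counted, not scorable
        gamma = feature_table[pair]
        score = f_score(gamma[pos], gamma[~pos])
        if score > best_score:
            best_score = score
            best_pair = pair
    assert best_pair is not None
    return ChannelBandSpec(
        channel=channel,
        fmin=grid.values[best_pair[0]],
        fmax=grid.values[best_pair[1]],
        fscore=best_score,
    )
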