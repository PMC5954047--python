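"""End-to-end COL training, prediction and evaluation.

Training runs mean removal -> per-channel optimal-band search -> decision
matrix -> sparse combiner; prediction applies the stored per-channel
bands and decision rules, combines with the learnt weights and bias and
squashes through the output-normalizing logistic.

The per-trial band-power features gamma(trial, channel, band) do not
depend on the labels, so cross-validation and the training-ratio sweep
precompute them once for the whole dataset and let every training fold
re-score its own subset; fold-wise band selection, decision fitting and
combiner training are unchanged and see only training trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import band_optimizer, channel_decision, sparse_combiner
from .dataio import COLConfig, COLModel, EpochsSet, ValidationError

logger = logging.getLogger("colbci")


# ---------------------------------------------------------------------------
# Feature cache
# ---------------------------------------------------------------------------


@dataclass
class BandFeatureCache:
    """gamma features of all trials at every scorable candidate band.

    ``tables[j]`` maps (nfmin, nfmax) grid-index pairs to length-N
    feature vectors for channel j.
    """

    grid: band_optimizer.FrequencyGrid
    mode: str
    tables: list[dict[tuple[int, int], np.ndarray]]

    def subset(self, idx: np.ndarray) -> "BandFeatureCache":
        return BandFeatureCache(
            grid=self.grid,
            mode=self.mode,
            tables=[{k: v[idx] for k, v in t.items()} for t in self.tables],
        )


def compute_band_features(epochs: EpochsSet, config: COLConfig) -> BandFeatureCache:
    """Preprocess (mean removal) and featurize every channel at every band."""
    grid = band_optimizer.frequency_grid(config.f0, config.theta, config.n_f)
    if grid.values[-1] >= epochs.fs / 2:
        raise ValidationError(
            f"grid top {grid.values[-1]:.2f} Hz reaches Nyquist ({epochs.fs / 2} Hz)"
        )
    # (N, C, M): mean-removed per trial per channel
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    data = np.moveaxis(data, 1, 2)
    tables = [
        band_optimizer.band_feature_table(
            data[:, j, :], epochs.fs, grid, config.band_search_mode, config.filter_order
        )
        for j in range(epochs.n_channels)
    ]
    return BandFeatureCache(grid=grid, mode=config.band_search_mode, tables=tables)


# ---------------------------------------------------------------------------
# Train / predict
# ---------------------------------------------------------------------------


def train_col(
    epochs: EpochsSet,
    config: COLConfig | None = None,
    cache: BandFeatureCache | None = None,
) -> COLModel:
    """Train a COL model on labeled epochs (deterministic, no RNG)."""
    if config is None:
        config = COLConfig()
    labels = epochs.require_labels()
    if cache is None:
        cache = compute_band_features(epochs, config)
    logger.info(
        "train_col: N=%d M=%d C=%d fs=%g config=%s",
        epochs.n_trials,
        epochs.n_samples,
        epochs.n_channels,
        epochs.fs,
        config.config_hash(),
    )
    band_specs = [
        band_optimizer.select_band(
            None,
            labels,
            j,
            epochs.fs,
            cache.grid,
            cache.mode,
            config.filter_order,
            feature_table=cache.tables[j],
        )
        for j in range(epochs.n_channels)
    ]
    gamma = _gamma_at_bands(cache, band_specs)
    decision_params = channel_decision.fit_decision_params(gamma, labels)
    P = channel_decision.build_decision_matrix(gamma, decision_params)
    alpha_eff = config.alpha * (
        epochs.n_trials if config.alpha_scaling == "per_trial" else 1.0
    )
    problem = sparse_combiner.CombinerProblem(
        P=P, y=labels, alpha=alpha_eff, bias_mode=config.bias_mode
    )
    w, b, trace = sparse_combiner.fit_weights(problem, config)
    logger.info(
        "train_col: %d/%d channels selected, solver stopped after %d iterations (%s)",
        int((w > 0).sum()),
        epochs.n_channels,
        trace.n_iter,
        trace.termination,
    )
    return COLModel(
        band_specs=band_specs,
        decision_params=decision_params,
        w=w,
        b=b,
        config=config,
        trace=trace,
        channel_names=list(epochs.channel_names),
    )


def _gamma_at_bands(cache: BandFeatureCache, band_specs) -> np.ndarray:
    """(N, C) feature matrix at each channel's selected band, from the cache."""
    values = cache.grid.values
    cols = []
    for j, bs in enumerate(band_specs):
        pair = (values.index(bs.fmin), values.index(bs.fmax))
        cols.append(cache.tables[j][pair])
    return np.column_stack(cols)


def _gamma_for_model(model: COLModel, epochs: EpochsSet) -> np.ndarray:
    """(N, C) feature matrix of new epochs at the model's stored bands."""
    from .band_optimizer import log_power_feature
    from .preprocess import BandPassSpec, bandpass, hilbert_envelope, remove_channel_means

    data = np.moveaxis(remove_channel_means(epochs.data), 1, 2)  # (N, C, M)
    cols = []
    for j, bs in enumerate(model.band_specs):
        spec = BandPassSpec(bs.fmin, bs.fmax, epochs.fs, model.config.filter_order)
        filtered = bandpass(data[:, j, :], spec, axis=-1)
        cols.append(log_power_feature(hilbert_envelope(filtered, axis=-1), axis=-1))
    return np.column_stack(cols)


def predict(model: COLModel, epochs: EpochsSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial raw score p, normalized probability and hard label.

    p = sum_c w_c P[:, c] + b; p_normal = S(beta (p - 0.5)); label is 1
    when p_normal >= 0.5 (ties go to class 1).
    """
    if epochs.n_channels != model.n_channels:
        raise ValidationError(
            f"model has {model.n_channels} channels, epochs have {epochs.n_channels}"
        )
    gamma = _gamma_for_model(model, epochs)
    P = channel_decision.build_decision_matrix(gamma, model.decision_params)
    p_raw = P @ model.w + model.b
    p_normal = sparse_combiner.normalize_prediction(p_raw, model.config.beta)
    labels = (p_normal >= 0.5).astype(np.int64)
    return p_raw, p_normal, labels


def _predict_from_cache(
    model: COLModel, cache: BandFeatureCache, idx: np.ndarray
) -> np.ndarray:
    """Hard labels for trials ``idx`` using cached features (identical math)."""
    gamma = _gamma_at_bands(cache.subset(idx), model.band_specs)
    P = channel_decision.build_decision_matrix(gamma, model.decision_params)
    p_normal = sparse_combiner.normalize_prediction(P @ model.w + model.b, model.config.beta)
    return (p_normal >= 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Cross-validated accuracy/F1 (percent) and model-size summary."""

    fold_accuracy: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)
    fold_n_selected: list[int] = field(default_factory=list)
    seed: int | None = None
    config: COLConfig | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) if len(self.fold_accuracy) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1, ddof=1)) if len(self.fold_f1) > 1 else 0.0

    @property
    def mean_n_selected(self) -> float:
        return float(np.mean(self.fold_n_selected))

    def summary(self) -> str:
        return (
            f"accuracy {self.mean_accuracy:.2f} +/- {self.sd_accuracy:.2f} %  "
            f"F1 {self.mean_f1:.2f} +/- {self.sd_f1:.2f} %  "
            f"channels {self.mean_n_selected:.1f}"
        )


def _fit_and_score(
    epochs: EpochsSet,
    labels: np.ndarray,
    cache: BandFeatureCache,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: COLConfig,
) -> tuple[float, float, int]:
    model = train_col(epochs.subset(train_idx), config, cache.subset(train_idx))
    pred = _predict_from_cache(model, cache, test_idx)
    truth = labels[test_idx]
    acc = 100.0 * accuracy_score(truth, pred)
    f1 = 100.0 * f1_score(truth, pred, pos_label=1, zero_division=0.0)
    return acc, f1, len(model.selected_channels)


def cross_validate(
    epochs: EpochsSet,
    k: int = 5,
    repeats: int = 5,
    config: COLConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation (accuracy and F1 in %)."""
    if config is None:
        config = COLConfig()
    labels = epochs.require_labels()
    if k < 2 or epochs.n_trials < 2 * k:
        raise ValidationError(f"need k >= 2 and N >= 2k, got k={k}, N={epochs.n_trials}")
    cache = compute_band_features(epochs, config)
    report = EvaluationReport(seed=seed, config=config)
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in splitter.split(np.zeros(epochs.n_trials), labels):
            acc, f1, n_sel = _fit_and_score(epochs, labels, cache, train_idx, test_idx, config)
            report.fold_accuracy.append(acc)
            report.fold_f1.append(f1)
            report.fold_n_selected.append(n_sel)
    logger.info("cross_validate k=%d repeats=%d seed=%d: %s", k, repeats, seed, report.summary())
    return report


def training_ratio_sweep(
    epochs: EpochsSet,
    ratios: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    repeats: int = 5,
    config: COLConfig | None = None,
    seed: int = 0,
) -> dict[float, EvaluationReport]:
    """Accuracy as the training fraction varies (repeated stratified splits)."""
    if config is None:
        config = COLConfig()
    labels = epochs.require_labels()
    n = epochs.n_trials
    n_classes = 2
    for r in ratios:
        if not 0.0 < r < 1.0:
            raise ValidationError(f"training ratio {r} outside (0, 1)")
        n_train = int(round(r * n))
        if n_train < n_classes or n - n_train < 1:
            raise ValidationError(f"training ratio {r} leaves a degenerate split for N={n}")
    cache = compute_band_features(epochs, config)
    out: dict[float, EvaluationReport] = {}
    for r in ratios:
        report = EvaluationReport(seed=seed, config=config)
        splitter = StratifiedShuffleSplit(
            n_splits=repeats, train_size=r, random_state=seed
        )
        for train_idx, test_idx in splitter.split(np.zeros(n), labels):
            acc, f1, n_sel = _fit_and_score(epochs, labels, cache, train_idx, test_idx, config)
            report.fold_accuracy.append(acc)
            report.fold_f1.append(f1)
            report.fold_n_selected.append(n_sel)
        out[r] = report
        logger.info("training ratio %.2f: %s", r, report.summary())
    return out


def crop_window(epochs: EpochsSet, t_start: float, t_end: float) -> EpochsSet:
    """Restrict every trial to [t_start, t_end) seconds relative to epoch onset."""
    duration = epochs.n_samples / epochs.fs
    if not 0 <= t_start < t_end <= duration + 1e-9:
        raise ValidationError(
            f"window ({t_start}, {t_end}) outside the {duration:.3f} s epoch"
        )
    i0 = int(round(t_start * epochs.fs))
    m = int(round((t_end - t_start) * epochs.fs))
    return EpochsSet(
        data=epochs.data[:, i0 : i0 + m, :],
        fs=epochs.fs,
        labels=epochs.labels,
        channel_names=list(epochs.channel_names),
        window=(t_start, t_end),
    )
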