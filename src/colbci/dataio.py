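"""Containers, file formats, serialization, configuration and logging.

The package works on epoched multichannel EEG: ``N`` trials of ``M``
samples over ``C`` channels, a sampling rate and optional binary labels.
Epochs are stored as a compressed npz archive with an exact float64
payload (member ``data``) plus a JSON metadata record (member ``meta``);
trained models are stored as plain JSON, which round-trips float64
exactly via the shortest-repr convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("colbci")

_MODEL_FORMAT_VERSION = 1
_EPOCHS_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Archive is structurally unreadable (missing members, bad version)."""


class ValidationError(ValueError):
    """Data violates a container invariant (non-finite, bad labels, ...)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class COLConfig:
    """Hyperparameters of the COL pipeline.

    Parameters
    ----------
    alpha : float
        l1 balance parameter of the combiner objective (default 0.01).
    f0, theta, n_f : float, float, int
        Geometric frequency grid {f0 * theta**k, k = 0..n_f} from which
        per-channel band edges are chosen (defaults 7 Hz, 1.22, 9).
    beta : float
        Slope of the output-normalizing logistic S(beta*(p-0.5)); 4 makes
        its derivative at p = 0.5 equal to 1.
    max_iter, rel_tol : int, float
        Solver termination: stop when the objective decrease falls below
        ``rel_tol`` of its value (the 0.9999 criterion for 1e-4), or after
        ``max_iter`` outer iterations.
    band_search_mode : {"fidelity", "full"}
        "fidelity" enumerates exactly the printed grid-search loops
        (zero-width candidates counted but unscorable); "full" scans all
        pairs fmin < fmax over the whole grid.
    bias_mode : {"corrected", "paper"}
        "corrected" (default) uses the least-squares minimizer
        b = -mean(Pw - y) and the centered gradient — the alternating
        minimization the method's derivation calls for. "paper" applies
        the sign-flipped rule b = +mean(Pw - y) exactly as the update is
        printed in the method's source, with the gradient that is
        algebraically consistent with it; that variant cannot recover
        multi-channel supports (see the methods note) and exists for
        faithfulness comparisons.
    alpha_scaling : {"per_trial", "literal"}
        "per_trial" (default) uses alpha * N as the effective penalty,
        reading alpha as the constant of a penalty proportional to the
        trial count — without this the data term grows with N while the
        penalty does not and sparsity washes out; "literal" uses alpha
        as-is.
    filter_order : int
        Butterworth order of the zero-phase band-pass.
    """

    alpha: float = 0.01
    f0: float = 7.0
    theta: float = 1.22
    n_f: int = 9
    beta: float = 4.0
    max_iter: int = 1000
    rel_tol: float = 1e-4
    band_search_mode: str = "fidelity"
    bias_mode: str = "corrected"
    alpha_scaling: str = "per_trial"
    filter_order: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValidationError("f0 must be positive")
        if self.theta <= 1:
            raise ValidationError("theta must exceed 1")
        if self.n_f < 1:
            raise ValidationError("n_f must be >= 1")
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.band_search_mode not in ("fidelity", "full"):
            raise ValidationError(f"unknown band_search_mode {self.band_search_mode!r}")
        if self.bias_mode not in ("paper", "corrected"):
            raise ValidationError(f"unknown bias_mode {self.bias_mode!r}")
        if self.alpha_scaling not in ("literal", "per_trial"):
            raise ValidationError(f"unknown alpha_scaling {self.alpha_scaling!r}")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValidationError("filter_order must be an even integer >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "COLConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Epochs container
# ---------------------------------------------------------------------------


@dataclass
class EpochsSet:
    """Epoched EEG: ``data`` is trial-major, shape (N trials, M samples, C channels)."""

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    channel_names: list[str] | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (trials, samples, channels), got shape {self.data.shape}"
            )
        n, m, c = self.data.shape
        if n < 1 or m < 2 or c < 1:
            raise ValidationError(f"need N >= 1, M >= 2, C >= 1; got {self.data.shape}")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        bad = ~np.isfinite(self.data)
        if bad.any():
            i, j, k = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample at trial {i}, sample {j}, channel {k}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValidationError(
                    f"labels must have length N={n}, got shape {self.labels.shape}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be in {0, 1}")
            self.labels = self.labels.astype(np.int64)
        if self.channel_names is not None:
            self.channel_names = [str(s) for s in self.channel_names]
            if len(self.channel_names) != c:
                raise ValidationError(
                    f"channel_names must have length C={c}, got {len(self.channel_names)}"
                )
        else:
            self.channel_names = [f"ch{j}" for j in range(c)]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("this operation requires labeled epochs")
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("supervised fitting requires both classes present")
        return self.labels

    def subset(self, idx: Sequence[int]) -> "EpochsSet":
        idx = np.asarray(idx)
        return EpochsSet(
            data=self.data[idx],
            fs=self.fs,
            labels=None if self.labels is None else self.labels[idx],
            channel_names=list(self.channel_names),
            window=self.window,
        )


def write_epochs(epochs: EpochsSet, path: str | Path) -> None:
    """Write an epochs archive; float64 payload is preserved exactly."""
    path = Path(path)
    if path.exists():
        logger.info("overwriting existing epochs archive %s", path)
    meta = {
        "format_version": _EPOCHS_FORMAT_VERSION,
        "fs": float(epochs.fs),
        "channel_names": epochs.channel_names,
        "labels": None if epochs.labels is None else epochs.labels.tolist(),
        "window": None if epochs.window is None else list(epochs.window),
    }
    with open(path, "wb") as fh:
        np.savez_compressed(fh, data=epochs.data, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8))
    logger.info("wrote epochs %s shape=%s", path, epochs.data.shape)


def read_epochs(path: str | Path) -> EpochsSet:
    """Read an epochs archive written by :func:`write_epochs`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path) as npz:
            if "data" not in npz or "meta" not in npz:
                raise FormatError(f"{path}: missing 'data' or 'meta' member")
            data = npz["data"]
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: unreadable epochs archive ({exc})") from exc
    if "fs" not in meta:
        raise FormatError(f"{path}: metadata lacks sampling rate")
    window = meta.get("window")
    return EpochsSet(
        data=data,
        fs=float(meta["fs"]),
        labels=meta.get("labels"),
        channel_names=meta.get("channel_names"),
        window=None if window is None else tuple(window),
    )


# ---------------------------------------------------------------------------
# Per-channel fit results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelBandSpec:
    """Optimal frequency band of one channel with its Fisher score."""

    channel: int
    fmin: float
    fmax: float
    fscore: float

    def __post_init__(self) -> None:
        if not self.fmin < self.fmax:
            raise ValidationError(f"channel {self.channel}: need fmin < fmax")


@dataclass(frozen=True)
class ChannelDecisionParams:
    """Class means, pooled variance and sign of one channel's feature."""

    mean_pos: float
    mean_neg: float
    variance: float
    sign: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValidationError("variance must be nonnegative")
        if self.sign not in (-1, 0, 1):
            raise ValidationError("sign must be -1, 0 or +1")
        if (self.sign == 0) != (self.mean_pos == self.mean_neg):
            raise ValidationError("sign must be 0 exactly when the class means agree")


@dataclass
class SolverTrace:
    """Per-iteration record of the alternating combiner solver."""

    objective: list[float] = field(default_factory=list)
    step: list[float] = field(default_factory=list)
    active: list[int] = field(default_factory=list)
    termination: str = ""

    @property
    def n_iter(self) -> int:
        return len(self.objective)

    def to_tsv(self) -> str:
        lines = ["iter\tobjective\tstep\tactive_channels"]
        for i, (h, eta, a) in enumerate(zip(self.objective, self.step, self.active)):
            lines.append(f"{i}\t{h!r}\t{eta!r}\t{a}")
        return "\n".join(lines) + "\n"


@dataclass
class COLModel:
    """Trained COL model: per-channel bands and decision rules, weights, bias."""

    band_specs: list[ChannelBandSpec]
    decision_params: list[ChannelDecisionParams]
    w: np.ndarray
    b: float
    config: COLConfig
    trace: SolverTrace | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if (self.w < 0).any():
            raise ValidationError("weights must be nonnegative")
        c = len(self.w)
        if len(self.band_specs) != c or len(self.decision_params) != c:
            raise ValidationError("need one band spec and one decision rule per channel")

    @property
    def n_channels(self) -> int:
        return len(self.w)

    @property
    def selected_channels(self) -> np.ndarray:
        return np.flatnonzero(self.w > 0)

    def weight_table(self) -> str:
        """Tab-separated channel table (index, name, fmin, fmax, weight)."""
        names = self.channel_names or [f"ch{j}" for j in range(self.n_channels)]
        lines = ["channel_index\tchannel_name\tfmin\tfmax\tweight"]
        for j in self.selected_channels:
            bs = self.band_specs[j]
            lines.append(
                f"{j}\t{names[j]}\t{bs.fmin!r}\t{bs.fmax!r}\t{float(self.w[j])!r}"
            )
        return "\n".join(lines) + "\n"


def save_model(model: COLModel, path: str | Path) -> None:
    """Serialize a model as JSON; floats round-trip exactly."""
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "b": model.b,
        "w": model.w.tolist(),
        "bands": [
            [bs.channel, bs.fmin, bs.fmax, bs.fscore] for bs in model.band_specs
        ],
        "decision": [
            [dp.mean_pos, dp.mean_neg, dp.variance, dp.sign]
            for dp in model.decision_params
        ],
        "channel_names": model.channel_names,
        "trace": None
        if model.trace is None
        else {
            "objective": model.trace.objective,
            "step": model.trace.step,
            "active": model.trace.active,
            "termination": model.trace.termination,
        },
    }
    Path(path).write_text(json.dumps(doc))
    logger.info(
        "saved model %s (config %s, %d selected channels)",
        path,
        model.config.config_hash(),
        len(model.selected_channels),
    )


def load_model(path: str | Path) -> COLModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise FormatError(f"{path}: missing format version")
    if doc["format_version"] != _MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {doc['format_version']} not supported"
        )
    trace = None
    if doc.get("trace") is not None:
        t = doc["trace"]
        trace = SolverTrace(
            objective=t["objective"],
            step=t["step"],
            active=t["active"],
            termination=t["termination"],
        )
    return COLModel(
        band_specs=[ChannelBandSpec(int(c), fmin, fmax, fs) for c, fmin, fmax, fs in doc["bands"]],
        decision_params=[
            ChannelDecisionParams(mp, mn, var, int(sg)) for mp, mn, var, sg in doc["decision"]
        ],
        w=np.asarray(doc["w"], dtype=np.float64),
        b=float(doc["b"]),
        config=COLConfig.from_dict(doc["config"]),
        trace=trace,
        channel_names=doc.get("channel_names"),
    )
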