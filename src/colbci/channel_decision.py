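"""Per-channel sigmoid decision rule and the N x C decision matrix P.

A channel's decision value for a trial with feature gamma is

    p = S( sign(mean_pos - mean_neg) / var
           * (gamma - (mean_pos + mean_neg) / 2) )

where S is the logistic function, the means are the class-conditional
feature means on the training set and var is the population variance of
the feature pooled over all training trials (both classes). The divisor
is the variance, not the standard deviation, exactly as the decision
rule is defined. When the class means coincide the channel is
uninformative and its decision value is the constant 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .dataio import ChannelDecisionParams, ValidationError


def fit_channel_decision(gamma: np.ndarray, labels: np.ndarray) -> ChannelDecisionParams:
    """Fit class means, pooled population variance and sign from training features."""
    gamma = np.asarray(gamma, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValidationError("both classes required to fit a channel decision rule")
    mean_pos = float(gamma[pos].mean())
    mean_neg = float(gamma[~pos].mean())
    return ChannelDecisionParams(
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        variance=float(gamma.var()),
        sign=int(np.sign(mean_pos - mean_neg)),
    )


def channel_probability(
    gamma: np.ndarray | float, params: ChannelDecisionParams
) -> np.ndarray | float:
    """Decision value(s) in (0, 1) for feature(s) ``gamma`` under ``params``."""
    gamma = np.asarray(gamma, dtype=np.float64)
    if params.sign == 0:
        out = np.full(gamma.shape, 0.5)
        return float(out) if out.ndim == 0 else out
    if params.variance <= 0:
        raise ValidationError("zero feature variance with distinct class means")
    midpoint = 0.5 * (params.mean_pos + params.mean_neg)
    scale = params.sign / params.variance
    out = expit(scale * (gamma - midpoint))
    # keep the open interval (0, 1) even when the logistic saturates in float64
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return float(out) if out.ndim == 0 else out


def fit_decision_params(
    gamma_matrix: np.ndarray, labels: np.ndarray
) -> list[ChannelDecisionParams]:
    """Fit one decision rule per column of an (N, C) feature matrix."""
    gamma_matrix = np.asarray(gamma_matrix, dtype=np.float64)
    return [fit_channel_decision(gamma_matrix[:, j], labels) for j in range(gamma_matrix.shape[1])]


def build_decision_matrix(
    gamma_matrix: np.ndarray, decision_params: list[ChannelDecisionParams]
) -> np.ndarray:
    """Decision matrix P: P[i, j] is trial i's decision value from channel j."""
    gamma_matrix = np.asarray(gamma_matrix, dtype=np.float64)
    if gamma_matrix.ndim != 2 or gamma_matrix.shape[1] != len(decision_params):
        raise ValidationError(
            f"feature matrix shape {gamma_matrix.shape} does not match "
            f"{len(decision_params)} channel decision rules"
        )
    cols = [
        channel_probability(gamma_matrix[:, j], p) for j, p in enumerate(decision_params)
    ]
    return np.column_stack(cols)
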