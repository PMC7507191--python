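"""Maximum-likelihood (optimal Bayesian) audio-visual cue combination.

The ideal observer combines the unisensory estimates S_V and S_A as a
weighted sum

    S_VA = w_V * S_V + w_A * S_A,
    w_V = sigma_A^2 / (sigma_A^2 + sigma_V^2),   w_A = 1 - w_V,

with weights inversely proportional to the unisensory variances, and the
predicted bimodal threshold satisfies

    sigma_VA^2 = sigma_V^2 * sigma_A^2 / (sigma_V^2 + sigma_A^2)
               <= min(sigma_V^2, sigma_A^2),

i.e. the combined variance is halved (threshold improves by sqrt(2)) when
the two unisensory thresholds are equal.

Under the symmetric conflict geometry (see
:mod:`tempobind.stimulus_design`) the model's predicted PSE shift in a
conflict condition, after normalizing by the no-conflict PSE, is
``delta * (w_V - w_A)``: zero for equal weights, ``-delta`` for complete
auditory dominance.  Predictions are always computed per subject from that
subject's own unisensory fits.

Sign convention: a positive shift means the PSE moves later than the
nominal midpoint.  With ``delta = +50`` (audio later than vision at the
probe) full auditory dominance gives a shift of -50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite, sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from .stimulus_design import MIDPOINT, VALID_DELTAS, modality_bisection_points

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class MLEPrediction:
    """Per-subject optimal-integration predictions.

    ``predicted_shift`` maps each conflict level delta to the predicted
    normalized PSE shift in ms.
    """

    w_v: float
    w_a: float
    sigma_va: float
    predicted_shift: Mapping[float, float]


def mle_weights(sigma_v: float, sigma_a: float) -> tuple[float, float]:
    """Reliability weights (w_V, w_A), inversely proportional to variance."""
    if sigma_v <= 0 or sigma_a <= 0:
        raise ValueError("unisensory thresholds must be positive")
    var_v, var_a = sigma_v**2, sigma_a**2
    w_v = var_a / (var_a + var_v)
    return w_v, 1.0 - w_v


def mle_threshold(sigma_v: float, sigma_a: float) -> float:
    """Predicted bimodal threshold sigma_VA; never exceeds min(sigma_V, sigma_A)."""
    if sigma_v <= 0 or sigma_a <= 0:
        raise ValueError("unisensory thresholds must be positive")
    var_v, var_a = sigma_v**2, sigma_a**2
    return sqrt(var_v * var_a / (var_v + var_a))


def mle_pse(w_v: float, w_a: float, s_v: float, s_a: float) -> float:
    """Weighted combination of the unisensory estimates."""
    if w_v < 0 or w_a < 0 or abs(w_v + w_a - 1.0) > 1e-6:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w_v * s_v + w_a * s_a


def predicted_conflict_shift(w_v: float, w_a: float, delta: float) -> float:
    """Predicted normalized PSE shift for one conflict level.

    Evaluates the weighted combination at the per-modality bisection
    points and subtracts the nominal midpoint; algebraically equal to
    ``delta * (w_V - w_A)``.
    """
    if delta not in VALID_DELTAS:
        raise ValueError(f"delta must be one of {VALID_DELTAS}, got {delta}")
    audio_point, visual_point = modality_bisection_points(delta)
    return mle_pse(w_v, w_a, visual_point, audio_point) - MIDPOINT


def normalize_pse(conflict_pse: float, noconflict_pse: float) -> float:
    """Constant-error correction: conflict PSE minus the subject's
    no-conflict PSE.  Apply the same subtraction to model predictions
    before comparing them with data."""
    if not (isfinite(conflict_pse) and isfinite(noconflict_pse)):
        raise ValueError("PSEs must be finite")
    return conflict_pse - noconflict_pse


def predict_from_unisensory(sigma_v: float, sigma_a: float) -> MLEPrediction:
    """Full prediction set from one subject's unisensory thresholds."""
    w_v, w_a = mle_weights(sigma_v, sigma_a)
    return MLEPrediction(
        w_v=w_v,
        w_a=w_a,
        sigma_va=mle_threshold(sigma_v, sigma_a),
        predicted_shift={d: predicted_conflict_shift(w_v, w_a, d) for d in VALID_DELTAS},
    )


def predictions_to_frame(
    predictions: Mapping[str, MLEPrediction]
) -> pd.DataFrame:
    """Per-subject prediction table.

    Shift columns use the convention: positive = PSE later than 500 ms.
    """
    rows = []
    for subject_id, pred in predictions.items():
        rows.append(
            {
                "subject_id": subject_id,
                "w_V": pred.w_v,
                "w_A": pred.w_a,
                "sigma_VA_pred_ms": pred.sigma_va,
                "shift_pred_neg_ms": pred.predicted_shift[-50.0],
                "shift_pred_zero_ms": pred.predicted_shift[0.0],
                "shift_pred_pos_ms": pred.predicted_shift[50.0],
            }
        )
    return pd.DataFrame(rows)
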