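"""Walking speed and its anthropometric normalization.

Mean speed is path length over duration.  Because taller/heavier people walk
faster in absolute terms, individual speed is normalized by dividing the
observed speed by the speed predicted from weight (kg) and height (cm) in an
ordinary least squares regression; within each regression scope the
normalized speeds then average to ~1 and group contrasts are no longer
driven by body size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


class SpeedError(ValueError):
    pass


@dataclass
class SpeedModel:
    intercept: float
    coef_weight: float  # (m/s) per kg
    coef_height: float  # (m/s) per cm
    scope: str  # e.g. the condition the model was fitted on
    r_squared: float
    n: int
    bse: np.ndarray | None = None  # standard errors (intercept, weight, height)

    def predict(self, weight_kg, height_cm) -> np.ndarray:
        return (self.intercept
                + self.coef_weight * np.asarray(weight_kg, float)
                + self.coef_height * np.asarray(height_cm, float))


@dataclass
class SpeedRecord:
    participant_id: str
    condition: str
    observed_speed: float
    predicted_speed: float
    normalized_speed: float


def mean_speed(duration_s: float, path_length_m: float = 10.0) -> float:
    """Mean walking speed over the path (m/s)."""
    if duration_s <= 0:
        raise SpeedError("duration must be positive")
    return path_length_m / duration_s


def fit_speed_model(speeds, weights, heights, scope: str = "all") -> SpeedModel:
    """OLS of speed on (weight, height) with intercept."""
    y = np.asarray(speeds, float)
    X = np.column_stack([np.asarray(weights, float), np.asarray(heights, float)])
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    if len(y) < 3:
        raise SpeedError(f"need >= 3 complete rows to fit the speed model, got {len(y)}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SpeedError("collinear predictors: weight/height regression is singular")
    fit = sm.OLS(y, Xc).fit()
    return SpeedModel(
        intercept=float(fit.params[0]),
        coef_weight=float(fit.params[1]),
        coef_height=float(fit.params[2]),
        scope=scope,
        r_squared=float(fit.rsquared),
        n=int(len(y)),
        bse=np.asarray(fit.bse, float),
    )


def normalize_speed(participant_id: str, condition: str, observed_speed: float,
                    weight_kg: float, height_cm: float,
                    model: SpeedModel) -> SpeedRecord | None:
    """Observed speed over model-predicted speed; None if prediction <= 0."""
    predicted = float(model.predict(weight_kg, height_cm))
    if predicted <= 0:
        log.warning("non-positive predicted speed for %s/%s; record excluded",
                    participant_id, condition)
        return None
    return SpeedRecord(participant_id, condition, float(observed_speed),
                       predicted, float(observed_speed) / predicted)


def normalize_cohort_speeds(table: pd.DataFrame, scope: str = "per-condition") -> pd.DataFrame:
    """Normalize every row of a cohort speed table.

    ``table`` needs columns participant_id, condition, observed_speed,
    weight_kg, height_cm.  ``scope`` = 'per-condition' fits one regression
    per speed condition (the conditions differ systematically in speed, so
    pooling them would confound the normalization); 'pooled' fits one model.
    """
    if scope not in ("per-condition", "pooled"):
        raise SpeedError(f"unknown scope {scope!r}")
    out = []
    grouping = table.groupby("condition") if scope == "per-condition" else [("all", table)]
    for label, sub in grouping:
        model = fit_speed_model(sub["observed_speed"], sub["weight_kg"],
                                sub["height_cm"], scope=str(label))
        for _, row in sub.iterrows():
            rec = normalize_speed(row["participant_id"], row["condition"],
                                  row["observed_speed"], row["weight_kg"],
                                  row["height_cm"], model)
            if rec is None:
                continue
            out.append({"participant_id": rec.participant_id,
                        "condition": rec.condition,
                        "observed_speed": rec.observed_speed,
                        "predicted_speed": rec.predicted_speed,
                        "normalized_speed": rec.normalized_speed})
    return pd.DataFrame(out)
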