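"""External-validation statistics for calibration models.

All statistics are computed on an external prediction set:

* RMSEP   = sqrt( sum_i (yhat_i - y_i)^2 / n )
* RSEP(%) = 100 * sqrt( sum_i (yhat_i - y_i)^2 / sum_i y_i^2 )
* Q^2     = 1 - sum_i (yhat_i - y_i)^2 / sum_i (y_i - ybar)^2, where ybar is
  the mean of the observed values over the evaluated (prediction) set
* R^2     = squared Pearson correlation between observed and predicted
* percent error = 100 * (pred - obs) / obs  (negative = under-prediction)

Using the prediction-set mean in the Q^2 denominator (rather than the
training mean) is a deliberate convention choice; it is the variant that
matches the published reference statistics this package benchmarks against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "rmsep",
    "rsep_percent",
    "q_squared",
    "r_squared",
    "percent_error",
    "PredictionReport",
]


def _pair(y_obs, y_pred, min_n: int = 1):
    o = np.asarray(y_obs, dtype=float).reshape(-1)
    p = np.asarray(y_pred, dtype=float).reshape(-1)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape[0]} observed vs {p.shape[0]} predicted")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {o.size}")
    return o, p


def rmsep(y_obs, y_pred) -> float:
    """Root mean square error of prediction."""
    o, p = _pair(y_obs, y_pred)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def rsep_percent(y_obs, y_pred) -> float:
    """Relative standard error of prediction, in percent of the observed
    vector's norm."""
    o, p = _pair(y_obs, y_pred)
    denom = np.sum(o**2)
    if denom == 0:
        raise ValueError("RSEP is undefined for all-zero observations")
    return float(100.0 * np.sqrt(np.sum((p - o) ** 2) / denom))


def q_squared(y_obs, y_pred) -> float:
    """External predictive ability, relative to predicting the evaluated
    set's own mean."""
    o, p = _pair(y_obs, y_pred, min_n=2)
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("Q^2 is undefined for constant observations")
    return float(1.0 - np.sum((p - o) ** 2) / ss_tot)


def r_squared(y_obs, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    o, p = _pair(y_obs, y_pred, min_n=2)
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        raise ValueError("R^2 is undefined when either vector is constant")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def percent_error(obs: float, pred: float) -> float:
    """Signed relative error in percent; positive = over-prediction."""
    if obs == 0:
        raise ValueError("percent error undefined for zero observed value")
    return float(100.0 * (pred - obs) / obs)


@dataclass
class PredictionReport:
    """Per-compound observed/predicted activities for one model plus the
    summary validation statistics."""

    compound_ids: list[str]
    y_obs: np.ndarray
    y_pred: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.y_obs, self.y_pred = _pair(self.y_obs, self.y_pred)
        if len(self.compound_ids) != self.y_obs.size:
            raise ValueError("one compound id per observation is required")

    @property
    def n(self) -> int:
        return self.y_obs.size

    def percent_errors(self) -> np.ndarray:
        return np.array([percent_error(o, p) for o, p in zip(self.y_obs, self.y_pred)])

    def summary(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "rmsep": rmsep(self.y_obs, self.y_pred),
            "rsep_percent": rsep_percent(self.y_obs, self.y_pred),
            "r_squared": r_squared(self.y_obs, self.y_pred),
            "q_squared": q_squared(self.y_obs, self.y_pred),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "observed": self.y_obs,
                "predicted": self.y_pred,
                "error_percent": self.percent_errors(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
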