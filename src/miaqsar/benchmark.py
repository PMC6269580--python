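"""Literature benchmark: the eight-compound external validation set of a
published 31-cephalosporin pixel-QSAR study of first acid dissociation
constants.

The tables give, for each held-out cephalosporin, the observed first pKa and
the value predicted by PCR, PLS and SPA-PLS calibrations (predictions as
printed, at two decimals).  They let the validation statistics in
:mod:`miaqsar.evaluation` be checked against independently published
numbers without access to the original structure drawings.

Note the printed predictions are rounded, so statistics recomputed from them
can differ from the study's own (computed at full precision) in the last
printed digit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import PredictionReport

__all__ = [
    "VALIDATION_COMPOUNDS",
    "OBSERVED_PKA",
    "PREDICTED_PKA",
    "validation_report",
    "validation_frame",
]

#: Series numbering of the eight prediction-set cephalosporins.
VALIDATION_COMPOUNDS = ("8", "24", "27", "20", "21", "25", "18", "19")

#: Observed first pKa of the prediction-set compounds.
OBSERVED_PKA = np.array([2.60, 1.62, 2.85, 2.10, 2.91, 3.20, 2.50, 2.03])

#: Predicted pKa per calibration method, as printed (two decimals).
PREDICTED_PKA = {
    "pcr": np.array([2.36, 1.97, 2.51, 2.58, 2.34, 2.60, 2.34, 1.79]),
    "pls": np.array([2.51, 1.90, 2.54, 2.50, 2.53, 2.67, 2.60, 2.17]),
    "spa-pls": np.array([2.56, 1.83, 2.81, 2.21, 2.57, 3.07, 2.42, 1.97]),
}


def validation_report(method: str) -> PredictionReport:
    """Prediction report for one benchmark calibration method."""
    if method not in PREDICTED_PKA:
        raise KeyError(f"unknown method {method!r}; expected one of {sorted(PREDICTED_PKA)}")
    return PredictionReport(
        compound_ids=list(VALIDATION_COMPOUNDS),
        y_obs=OBSERVED_PKA,
        y_pred=PREDICTED_PKA[method],
        method=method,
    )


def validation_frame() -> pd.DataFrame:
    """All three methods side by side, one row per validation compound."""
    df = pd.DataFrame({"compound_id": VALIDATION_COMPOUNDS, "observed": OBSERVED_PKA})
    for method, pred in PREDICTED_PKA.items():
        df[method] = pred
    return df
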