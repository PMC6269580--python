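"""Latent-variable calibration: PCA exploration, PCR and PLS regression,
leave-one-out RMSECV, and the F-test rule for choosing the number of latent
variables.

Both calibrations are single-response and operate on mean-centered data:
columns are centered but not autoscaled, and the response is centered but
not scaled.  PCR regresses the response on the leading principal-component
scores; PLS is the single-y NIPALS algorithm, where each component's weight
vector is the (closed-form) covariance direction between the deflated
predictors and the response residual, so the fit is deterministic with no
iterative convergence tolerance.

At full rank both methods reach the interpolation limit and coincide with
ordinary least squares — a property the test suite exploits as an oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "CalibrationModel",
    "CvCurve",
    "pca",
    "fit_pcr",
    "fit_pls",
    "loo_rmsecv",
    "choose_n_lv",
    "predict",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


@dataclass
class CalibrationModel:
    """A fitted PCR or PLS calibration.

    ``regression_vector`` maps centered predictors to the centered response;
    :func:`predict` applies the stored training means so raw rows can be
    scored directly.  ``column_map`` (optional) records the source pixel of
    every coefficient; ``image_shape``/``anchor`` make the model applicable
    to freshly drawn images.
    """

    method: str  # "pcr" or "pls"
    n_lv: int
    regression_vector: np.ndarray
    x_means: np.ndarray
    y_mean: float
    scores: np.ndarray = field(repr=False, default=None)
    loadings: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray | None = field(repr=False, default=None)  # PLS only
    column_map: np.ndarray | None = None
    image_shape: tuple[int, int] | None = None
    anchor: tuple[int, int] | None = None

    def predict(self, x_new) -> np.ndarray:
        return predict(self, x_new)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_lv": int(self.n_lv),
            "regression_vector": np.asarray(self.regression_vector).tolist(),
            "x_means": np.asarray(self.x_means).tolist(),
            "y_mean": float(self.y_mean),
        }
        if self.column_map is not None:
            d["column_map"] = np.asarray(self.column_map).tolist()
        if self.image_shape is not None:
            d["image_shape"] = list(self.image_shape)
        if self.anchor is not None:
            d["anchor"] = list(self.anchor)
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            method=d["method"],
            n_lv=int(d["n_lv"]),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            x_means=np.asarray(d["x_means"], dtype=float),
            y_mean=float(d["y_mean"]),
            column_map=np.asarray(d["column_map"], dtype=int) if "column_map" in d else None,
            image_shape=tuple(d["image_shape"]) if "image_shape" in d else None,
            anchor=tuple(d["anchor"]) if "anchor" in d else None,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CvCurve:
    """RMSECV as a function of the number of latent variables."""

    n_lvs: list[int]
    rmsecv: list[float]
    n: int  # number of held-out predictions behind each RMSECV value
    method: str = ""
    chosen_n_lv: int | None = None
    rule: str | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"n_lv": self.n_lvs, "rmsecv": self.rmsecv}).to_csv(path, index=False)


def _center(x: np.ndarray, y: np.ndarray):
    xm = x.mean(axis=0)
    ym = float(y.mean())
    return x - xm, y - ym, xm, ym


def _check_n_lv(n_lv: int, n: int, p: int) -> None:
    limit = min(n - 1, p)
    if not 1 <= n_lv <= limit:
        raise ValueError(f"n_lv must be in [1, {limit}] for a {n}x{p} matrix, got {n_lv}")


def pca(x, n_components: int):
    """Principal components of the (centered) descriptor matrix.

    Returns ``(scores, loadings, explained_variance_ratio)`` with orthonormal
    loadings of shape (p, k).  If ``n_components`` exceeds the matrix rank
    the decomposition is truncated with a warning.
    """
    values = _as_array(x)
    n, p = values.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}] for a {n}x{p} matrix"
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values)
    sv = model.singular_values_
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv[0] > 0 else 0
    if rank == 0:
        raise ValueError("matrix has rank 0: no principal components exist")
    if rank < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        scores = scores[:, :rank]
        return scores, model.components_[:rank].T, model.explained_variance_ratio_[:rank]
    return scores, model.components_.T, model.explained_variance_ratio_


def fit_pcr(x_train, y_train, n_lv: int, **meta) -> CalibrationModel:
    """Principal component regression: regress the centered response on the
    first ``n_lv`` PCA score columns and fold the coefficients back to pixel
    space."""
    x = _as_array(x_train)
    y = np.asarray(y_train, dtype=float)
    n, p = x.shape
    _check_n_lv(n_lv, n, p)
    xc, yc, xm, ym = _center(x, y)

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
    if n_lv > rank:
        raise ValueError(f"n_lv {n_lv} exceeds the matrix rank {rank}")
    scores = u[:, :n_lv] * s[:n_lv]
    # scores are orthogonal with squared norms s^2, so the LS coefficients
    # have the closed form below
    coef = (scores.T @ yc) / s[:n_lv] ** 2
    b = vt[:n_lv].T @ coef
    return CalibrationModel(
        method="pcr",
        n_lv=n_lv,
        regression_vector=b,
        x_means=xm,
        y_mean=ym,
        scores=scores,
        loadings=vt[:n_lv].T,
        **meta,
    )


def fit_pls(x_train, y_train, n_lv: int, **meta) -> CalibrationModel:
    """Single-response NIPALS PLS with x- and y-deflation."""
    x = _as_array(x_train)
    y = np.asarray(y_train, dtype=float)
    n, p = x.shape
    _check_n_lv(n_lv, n, p)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    xc, yc, xm, ym = _center(x, y)

    x_scale = np.linalg.norm(xc)
    y_scale = np.linalg.norm(yc)
    w_mat = np.zeros((p, n_lv))
    p_mat = np.zeros((p, n_lv))
    t_mat = np.zeros((n, n_lv))
    q_vec = np.zeros(n_lv)
    xd, yd = xc.copy(), yc.copy()
    n_done = n_lv
    for a in range(n_lv):
        w = xd.T @ yd  # covariance direction — closed form for single y
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * max(x_scale * y_scale, 1.0):
            if np.linalg.norm(xd) <= 1e-12 * max(x_scale, 1.0):
                raise ValueError(
                    f"n_lv {n_lv} exceeds the effective rank; failed at component {a + 1}"
                )
            # predictors still alive but the response residual is orthogonal
            # to every column: further components carry nothing
            warnings.warn(
                f"response residual uncorrelated with predictors; stopping at "
                f"{a} of {n_lv} components",
                stacklevel=2,
            )
            n_done = a
            break
        w /= wn
        t = xd @ w
        tt = float(t @ t)
        p_load = xd.T @ t / tt
        q = float(yd @ t) / tt
        xd -= np.outer(t, p_load)
        yd = yd - q * t
        w_mat[:, a], p_mat[:, a], t_mat[:, a], q_vec[a] = w, p_load, t, q

    w_mat, p_mat, t_mat, q_vec = (
        w_mat[:, :n_done], p_mat[:, :n_done], t_mat[:, :n_done], q_vec[:n_done]
    )
    if n_done == 0:
        b = np.zeros(p)
    else:
        # rotate weights so the regression vector acts on undeflated data
        r_mat = w_mat @ np.linalg.inv(p_mat.T @ w_mat)
        b = r_mat @ q_vec
    return CalibrationModel(
        method="pls",
        n_lv=n_done,
        regression_vector=b,
        x_means=xm,
        y_mean=ym,
        scores=t_mat,
        loadings=p_mat,
        weights=w_mat,
        **meta,
    )


_FITTERS = {"pcr": fit_pcr, "pls": fit_pls}


def predict(model: CalibrationModel, x_new) -> np.ndarray:
    """Apply a calibration to raw (uncentered) rows over the same retained
    columns the model was trained on."""
    x = _as_array(x_new)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.x_means.shape[0]:
        raise ValueError(
            f"column mismatch: model expects {model.x_means.shape[0]} columns, got {x.shape[1]}"
        )
    cmap = getattr(x_new, "column_map", None)
    if cmap is not None and model.column_map is not None:
        if not np.array_equal(np.asarray(cmap), np.asarray(model.column_map)):
            ours = {tuple(rc) for rc in np.asarray(model.column_map)}
            theirs = {tuple(rc) for rc in np.asarray(cmap)}
            missing = sorted(ours - theirs)[:5]
            raise ValueError(f"retained pixels differ from the model's; e.g. missing {missing}")
    return (x - model.x_means) @ model.regression_vector + model.y_mean


def loo_rmsecv(x_train, y_train, method: str = "pls", lv_range=None) -> CvCurve:
    """Leave-one-out RMSECV over candidate latent-variable counts.

    Each fold refits (and re-centers) on the remaining rows and predicts the
    held-out row; candidates an individual fold cannot support are skipped
    with a warning.
    """
    x = _as_array(x_train)
    y = np.asarray(y_train, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 samples")
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_FITTERS)}")
    fit = _FITTERS[method]
    if lv_range is None:
        lv_range = range(1, min(n - 2, p) + 1)

    n_lvs, curve = [], []
    for lv in lv_range:
        if lv > min(n - 2, p):  # a fold has n-1 rows, so at most n-2 LVs
            warnings.warn(f"skipping n_lv={lv}: not supported by every LOO fold", stacklevel=2)
            continue
        press = 0.0
        ok = True
        for i in range(n):
            mask = np.arange(n) != i
            try:
                m = fit(x[mask], y[mask], lv)
            except ValueError as exc:
                warnings.warn(f"skipping n_lv={lv}: fold {i} failed ({exc})", stacklevel=2)
                ok = False
                break
            press += float((predict(m, x[i])[0] - y[i]) ** 2)
        if ok:
            n_lvs.append(int(lv))
            curve.append(float(np.sqrt(press / n)))
    if not n_lvs:
        raise ValueError("no latent-variable candidate could be cross-validated")
    return CvCurve(n_lvs=n_lvs, rmsecv=curve, n=n, method=method)


def choose_n_lv(curve: CvCurve, alpha: float = 0.25) -> int:
    """Haaland-Thomas rule: prefer the most parsimonious model whose RMSECV
    is not significantly worse than the global minimum.

    ``F = (RMSECV_h / RMSECV_min)^2`` is compared against the F(n, n)
    quantile at probability 1 - alpha; the smallest h (with fewer LVs than
    the argmin) passing the test is chosen, else the argmin itself.
    """
    if not curve.n_lvs:
        raise ValueError("empty cross-validation curve")
    rmse = np.asarray(curve.rmsecv)
    imin = int(np.argmin(rmse))
    f_crit = f_dist.ppf(1.0 - alpha, curve.n, curve.n)
    chosen = imin
    for h in range(imin):
        ratio = np.inf if rmse[imin] == 0 else (rmse[h] / rmse[imin]) ** 2
        if ratio < f_crit:
            chosen = h
            break
    curve.chosen_n_lv = curve.n_lvs[chosen]
    curve.rule = f"haaland-thomas F({curve.n},{curve.n}) alpha={alpha}"
    return curve.n_lvs[chosen]
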