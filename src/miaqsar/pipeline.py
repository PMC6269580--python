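"""End-to-end orchestration of the pixel-QSAR analysis.

Stage order follows the method's canonical workflow: acquire structure
images (synthetic or from disk) -> align on the common anchor -> unfold to
the descriptor matrix -> Kennard-Stone split -> zero-variance filtering
(judged on training rows only, so prediction compounds never leak into the
filter) -> optional SPA pixel selection scored on an inner Kennard-Stone
validation split of the training set -> leave-one-out RMSECV and F-test
choice of latent variables -> final PCR / PLS / SPA-PLS fits -> external
validation report.

Everything random flows from one seed; rerunning a configuration reproduces
every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import imaging, modeling, selection as selection_mod
from .evaluation import PredictionReport
from .imaging import DescriptorMatrix, StructureImage
from .modeling import CalibrationModel, CvCurve
from .selection import SelectionResult
from .splitting import SplitAssignment, kennard_stone
from .synthetic import GeneratorConfig, generate

logger = logging.getLogger("miaqsar.pipeline")

__all__ = ["RunConfig", "RunResult", "run", "predict_new"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one input source is used: a synthetic generator configuration,
    or an image directory with ``activities.csv`` and an anchor sidecar.
    """

    synthetic: GeneratorConfig | None = None
    image_dir: str | Path | None = None
    activities_csv: str | Path | None = None
    anchors_csv: str | Path | None = None
    anchor: tuple[int, int] | None = None  # common anchor; defaults to the images' own
    threshold: float = 0.5
    n_train: int = 23
    filter_scope: str = "train"  # "train" (leakage-safe) or "all"
    selection: bool = True
    n_min: int = 2
    n_max: int | None = None
    inner_val_fraction: float = 0.3
    methods: tuple[str, ...] = ("pcr", "pls", "spa-pls")
    max_lv: int = 10
    alpha: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.image_dir is None):
            raise ValueError("configure exactly one input source: synthetic or image_dir")
        if self.filter_scope not in ("train", "all"):
            raise ValueError("filter_scope must be 'train' or 'all'")
        for m in self.methods:
            if m not in ("pcr", "pls", "spa-pls"):
                raise ValueError(f"unknown method {m!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("image_dir", "activities_csv", "anchors_csv"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


@dataclass
class RunResult:
    """In-memory counterpart of the artifacts a run writes to disk."""

    config: RunConfig
    matrix: DescriptorMatrix
    split: SplitAssignment
    selection: SelectionResult | None
    curves: dict[str, CvCurve]
    models: dict[str, CalibrationModel]
    reports: dict[str, PredictionReport]
    summary: dict
    truth: dict | None = None
    images: list[StructureImage] = field(default_factory=list, repr=False)


def _acquire(config: RunConfig):
    if config.synthetic is not None:
        gen_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        ds = generate(gen_cfg)
        logger.info("generated %d synthetic images (seed=%d)", len(ds.images), config.seed)
        return ds.images, np.asarray(ds.activities), ds.truth
    images, activities = imaging.load_directory(
        config.image_dir,
        threshold=config.threshold,
        activities_csv=config.activities_csv,
        anchors_csv=config.anchors_csv,
    )
    if activities is None:
        raise ValueError("an activities.csv is required for model building")
    logger.info("loaded %d images from %s", len(images), config.image_dir)
    return images, activities.to_numpy(dtype=float), None


def run(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write all artifacts under
    ``out_dir``."""
    config.validate()
    images, y, truth = _acquire(config)
    n = len(images)
    if not 2 <= config.n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}]")

    anchor = config.anchor or images[0].anchor
    aligned = imaging.align(images, anchor)
    full = imaging.unfold(aligned)
    logger.info(
        "aligned and unfolded: %d x %d matrix (%dx%d workspace, anchor %s)",
        full.n_compounds, full.n_columns, *full.image_shape, anchor,
    )

    degenerate = config.n_train == n
    if degenerate:
        split = SplitAssignment(training_indices=list(range(n)), prediction_indices=[])
        logger.info("n_train equals n_compounds: validation stage will be skipped")
    else:
        split = kennard_stone(full, config.n_train)
        logger.info(
            "Kennard-Stone split: %d training / %d prediction",
            split.n_train, len(split.prediction_indices),
        )
    train = np.array(split.training_indices)
    pred_rows = np.array(split.prediction_indices, dtype=int)

    filt = imaging.drop_zero_variance(
        full, rows=train if config.filter_scope == "train" else None
    )
    logger.info(
        "zero-variance filter (%s rows): retained %d of %d columns",
        config.filter_scope, filt.n_columns, full.n_columns,
    )

    x_train, y_train = filt.values[train], y[train]

    sel: SelectionResult | None = None
    if config.selection and "spa-pls" in config.methods:
        n_inner = max(2, min(round((1 - config.inner_val_fraction) * len(train)), len(train) - 1))
        inner = kennard_stone(x_train, n_inner)
        xi, xv = x_train[inner.training_indices], x_train[inner.prediction_indices]
        yi, yv = y_train[inner.training_indices], y_train[inner.prediction_indices]
        means = xi.mean(axis=0)
        n_max = config.n_max
        if n_max is None:
            n_max = min(20, len(yi) - 2, xi.shape[1])
        sel = selection_mod.spa_select(
            xi - means, yi, xv - means, yv, n_min=config.n_min, n_max=n_max
        )
        logger.info(
            "SPA selected %d pixels (start column %d, validation RMSE %.4g)",
            sel.n_selected, sel.winning_start, sel.winning_score,
        )

    curves: dict[str, CvCurve] = {}
    models: dict[str, CalibrationModel] = {}
    reports: dict[str, PredictionReport] = {}
    pred_ids = [filt.compound_ids[i] for i in pred_rows] if filt.compound_ids else [str(i) for i in pred_rows]
    for method in config.methods:
        if method == "spa-pls":
            if sel is None:
                logger.info("spa-pls requested without selection: skipping")
                continue
            cols = np.array(sel.selected_columns)
            base_method = "pls"
        else:
            cols = np.arange(filt.n_columns)
            base_method = method
        xt = x_train[:, cols]
        lv_max = min(config.max_lv, len(train) - 2, len(cols))
        curve = modeling.loo_rmsecv(xt, y_train, method=base_method, lv_range=range(1, lv_max + 1))
        n_lv = modeling.choose_n_lv(curve, alpha=config.alpha)
        model = _FIT[base_method](
            xt, y_train, n_lv,
            column_map=filt.column_map[cols],
            image_shape=filt.image_shape,
            anchor=anchor,
        )
        model.method = method
        curves[method], models[method] = curve, model
        logger.info("%s: %d latent variables (RMSECV %.4g)", method,
                    n_lv, curve.rmsecv[curve.n_lvs.index(n_lv)])
        if not degenerate:
            y_hat = modeling.predict(model, filt.values[pred_rows][:, cols])
            reports[method] = PredictionReport(
                compound_ids=pred_ids, y_obs=y[pred_rows], y_pred=y_hat, method=method
            )
            logger.info("%s: external RMSEP %.4g", method, reports[method].summary()["rmsep"])

    summary = {
        "seed": config.seed,
        "n_compounds": n,
        "n_train": split.n_train,
        "n_prediction": len(split.prediction_indices),
        "workspace": list(full.image_shape),
        "anchor": list(anchor),
        "columns_total": full.n_columns,
        "columns_retained": filt.n_columns,
        "selection": None
        if sel is None
        else {
            "n_selected": sel.n_selected,
            "columns": [int(c) for c in sel.selected_columns],
            "pixels": filt.column_map[sel.selected_columns].tolist(),
            "winning_start": int(sel.winning_start),
            "validation_rmse": sel.winning_score,
        },
        "models": {
            m: {
                "n_lv": models[m].n_lv,
                **(reports[m].summary() if m in reports else {"method": m}),
            }
            for m in models
        },
    }

    if out_dir is not None:
        _write_artifacts(Path(out_dir), config, aligned, full, filt, split, sel, curves, models, reports, summary)

    return RunResult(
        config=config, matrix=filt, split=split, selection=sel, curves=curves,
        models=models, reports=reports, summary=summary, truth=truth, images=aligned,
    )


_FIT = {"pcr": modeling.fit_pcr, "pls": modeling.fit_pls}


def _write_artifacts(out, config, images, full, filt, split, sel, curves, models, reports, summary):
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True, default=str)
    with open(out / "descriptors.json", "w") as fh:
        json.dump(
            {
                "n_compounds": full.n_compounds,
                "workspace": list(full.image_shape),
                "columns_total": full.n_columns,
                "columns_retained": filt.n_columns,
            },
            fh, indent=1, sort_keys=True,
        )
    split.to_csv(out / "split.csv", compound_ids=filt.compound_ids)
    if sel is not None:
        with open(out / "selection.json", "w") as fh:
            json.dump(summary["selection"], fh, indent=1, sort_keys=True)
        mean_img = np.mean([im.pixels for im in images], axis=0)
        rgb = selection_mod.overlay_selection(mean_img, filt.column_map[sel.selected_columns])
        Image.fromarray(rgb, mode="RGB").save(out / "selection_overlay.png")
    for m, curve in curves.items():
        curve.to_csv(out / f"cv_{m}.csv")
    for m, model in models.items():
        model.to_json(out / f"model_{m}.json")
    if reports:
        frames = []
        for m, rep in reports.items():
            df = rep.to_frame()
            df.insert(0, "method", m)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(out / "predictions.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("artifacts written to %s", out)


def predict_new(
    model: CalibrationModel | str | Path,
    image_paths: list[str | Path],
    anchors_csv: str | Path | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score freshly drawn compounds with a serialized (or in-memory)
    calibration: align to the model's anchor, unfold, keep the model's
    retained pixels, predict."""
    if not isinstance(model, CalibrationModel):
        model = CalibrationModel.from_json(model)
    if model.column_map is None or model.image_shape is None or model.anchor is None:
        raise ValueError("model lacks pixel provenance (column_map/image_shape/anchor)")

    anchors = imaging.read_anchor_sidecar(anchors_csv) if anchors_csv else {}
    images = []
    for p in image_paths:
        p = Path(p)
        images.append(imaging.load_image(p, threshold=threshold, anchor=anchors.get(p.stem)))
    for im in images:
        if im.shape != tuple(model.image_shape):
            raise ValueError(
                f"{im.compound_id}: image is {im.shape}, model expects {tuple(model.image_shape)}"
            )
        if im.anchor is None:
            im.anchor = tuple(model.anchor)

    aligned = imaging.align(images, tuple(model.anchor))
    full = imaging.unfold(aligned)
    h, w = full.image_shape
    lin = model.column_map[:, 0] * w + model.column_map[:, 1]
    preds = modeling.predict(model, full.values[:, lin])
    return pd.DataFrame(
        {"compound_id": [im.compound_id for im in aligned], "predicted": preds}
    )
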