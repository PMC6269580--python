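"""Structure-image handling: load, binarize, align, unfold, filter, center.

In pixel-based QSAR the descriptor of a compound is the flattened binary
bitmap of its 2D structure drawing.  All drawings share a fixed workspace
(default 240 wide x 160 tall) and a fixed *anchor* pixel — an atom position
common to the whole series (classically the sulfur of a fused ring system) —
so that after translation onto the common anchor the images superimpose and
homologous pixels end up in the same matrix column.

Coordinates are 0-based ``(row, col)`` internally, row-major scan order for
unfolding.  Drawing-convention coordinates in sidecar files are 1-based and
width-first ``(col, row)``; they are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "StructureImage",
    "DescriptorMatrix",
    "load_image",
    "load_directory",
    "align",
    "unfold",
    "fold",
    "drop_zero_variance",
    "center",
]


@dataclass
class StructureImage:
    """One compound's binary pixel grid plus its anchor coordinate.

    ``pixels`` is a (height, width) array with values in {0, 1}; foreground
    (strokes) is 1.  ``anchor`` is a 0-based (row, col) pixel that must be
    foreground, used for superposition.
    """

    pixels: np.ndarray
    anchor: tuple[int, int] | None = None
    compound_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"{self.compound_id or 'image'}: pixels must be a non-empty 2D grid")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.compound_id or 'image'}: pixel values must be binary 0/1")
        if self.anchor is not None:
            r, c = self.anchor
            h, w = self.pixels.shape
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"{self.compound_id or 'image'}: anchor {self.anchor} outside {h}x{w} image"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DescriptorMatrix:
    """Compounds x retained-pixels matrix with pixel provenance.

    ``column_map[j]`` is the (row, col) source coordinate of column j;
    ``removed_columns`` holds coordinates eliminated by zero-variance
    filtering so that ``n_columns + len(removed_columns)`` always equals
    height * width of the source images.
    """

    values: np.ndarray
    column_map: np.ndarray  # (n_columns, 2) int
    image_shape: tuple[int, int]
    removed_columns: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    column_means: np.ndarray | None = None
    centered: bool = False
    compound_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.column_map = np.asarray(self.column_map, dtype=int)
        self.removed_columns = np.asarray(self.removed_columns, dtype=int).reshape(-1, 2)
        if self.column_map.shape != (self.values.shape[1], 2):
            raise ValueError("column_map length must equal the number of columns")
        h, w = self.image_shape
        if self.values.shape[1] + len(self.removed_columns) != h * w:
            raise ValueError("retained + removed columns must cover the full pixel grid")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        return [f"r{r}c{c}" for r, c in self.column_map]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names())
        if self.compound_ids is not None:
            df.insert(0, "compound_id", self.compound_ids)
        df.to_csv(path, index=False)


def load_image(
    path: str | Path,
    threshold: float = 0.5,
    anchor: tuple[int, int] | None = None,
    compound_id: str | None = None,
) -> StructureImage:
    """Read a PNG/BMP raster and binarize it to a stroke-foreground grid.

    RGB is collapsed to luminance; pixels at or above ``threshold`` of the
    intensity range become 1.  If the resulting foreground is the majority
    class the polarity is inverted, so dark-on-light drawings (the usual
    export) end up with strokes as foreground.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=float)
    except Exception as exc:  # noqa: BLE001 - surface decoder failures uniformly
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    grid = (arr >= threshold * 255.0).astype(np.uint8)
    if grid.mean() > 0.5:  # foreground must be the minority (strokes)
        grid = 1 - grid
    return StructureImage(
        pixels=grid,
        anchor=anchor,
        compound_id=compound_id if compound_id is not None else path.stem,
    )


def read_anchor_sidecar(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a ``compound_id,anchor_col,anchor_row`` CSV (1-based, width-first)
    and return 0-based (row, col) anchors keyed by compound id."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "anchor_col", "anchor_row"}
    if not required.issubset(df.columns):
        raise ValueError(f"anchor sidecar must have columns {sorted(required)}")
    return {
        str(row.compound_id): (int(row.anchor_row) - 1, int(row.anchor_col) - 1)
        for row in df.itertuples()
    }


def load_directory(
    directory: str | Path,
    threshold: float = 0.5,
    activities_csv: str | Path | None = None,
    anchors_csv: str | Path | None = None,
) -> tuple[list[StructureImage], pd.Series | None]:
    """Load every PNG/BMP in ``directory`` (sorted by name) with optional
    activities (``compound_id,activity``) and anchor sidecar CSVs."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".png", ".bmp"))
    if not paths:
        raise ValueError(f"no PNG/BMP images found in {directory}")
    if anchors_csv is None and (directory / "anchors.csv").exists():
        anchors_csv = directory / "anchors.csv"
    anchors = read_anchor_sidecar(anchors_csv) if anchors_csv is not None else {}
    images = [load_image(p, threshold=threshold, anchor=anchors.get(p.stem)) for p in paths]

    if activities_csv is None and (directory / "activities.csv").exists():
        activities_csv = directory / "activities.csv"
    activities = None
    if activities_csv is not None:
        df = pd.read_csv(activities_csv, dtype={"compound_id": str})
        activities = df.set_index("compound_id")["activity"].reindex(
            [im.compound_id for im in images]
        )
        if activities.isna().any():
            missing = activities.index[activities.isna()].tolist()
            raise ValueError(f"activities.csv is missing compounds: {missing}")
    return images, activities


def _translate(pixels: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a grid by (dr, dc); vacated pixels are background, pixels moved
    outside the frame are dropped."""
    out = np.zeros_like(pixels)
    h, w = pixels.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = pixels[src_r, src_c]
    return out


def align(images: list[StructureImage], anchor: tuple[int, int]) -> list[StructureImage]:
    """Translate every image so its own anchor lands on the common anchor."""
    if not images:
        return []
    shape = images[0].shape
    aligned = []
    for im in images:
        if im.shape != shape:
            raise ValueError(
                f"image dimensions differ: {im.compound_id or '?'} is "
                f"{im.shape}, expected {shape}"
            )
        if im.anchor is None:
            raise ValueError(f"image {im.compound_id or '?'} has no anchor coordinate")
        dr = anchor[0] - im.anchor[0]
        dc = anchor[1] - im.anchor[1]
        aligned.append(
            StructureImage(
                pixels=_translate(im.pixels, dr, dc),
                anchor=anchor,
                compound_id=im.compound_id,
            )
        )
    return aligned


def unfold(images: list[StructureImage]) -> DescriptorMatrix:
    """Stack images row-wise: row i is image i scanned in row-major order."""
    if not images:
        raise ValueError("unfold requires at least one image")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError(
                f"image dimensions differ: {im.compound_id or '?'} is "
                f"{im.shape}, expected {shape}"
            )
    h, w = shape
    values = np.stack([im.pixels.reshape(-1) for im in images]).astype(float)
    rows, cols = np.indices(shape)
    column_map = np.column_stack([rows.reshape(-1), cols.reshape(-1)])
    return DescriptorMatrix(
        values=values,
        column_map=column_map,
        image_shape=shape,
        compound_ids=[im.compound_id for im in images],
    )


def fold(m: DescriptorMatrix, fill: float = 0.0) -> list[np.ndarray]:
    """Inverse of :func:`unfold`: rebuild one (height, width) grid per row.

    Columns removed by filtering are restored as ``fill``.
    """
    h, w = m.image_shape
    grids = []
    lin = m.column_map[:, 0] * w + m.column_map[:, 1]
    for row in m.values:
        g = np.full(h * w, fill, dtype=float)
        g[lin] = row
        grids.append(g.reshape(h, w))
    return grids


def drop_zero_variance(m: DescriptorMatrix, rows: np.ndarray | None = None) -> DescriptorMatrix:
    """Remove columns constant across compounds (scaffold / blank workspace).

    When ``rows`` is given the variance is judged on that subset only (the
    training rows), so prediction compounds never influence which pixels are
    kept.
    """
    if m.centered:
        raise ValueError("zero-variance filtering must run on the uncentered matrix")
    sub = m.values if rows is None else m.values[np.asarray(rows)]
    varying = sub.max(axis=0) != sub.min(axis=0)
    if not varying.any():
        raise ValueError("every column is constant: no pixel varies across compounds")
    removed = np.vstack([m.removed_columns, m.column_map[~varying]])
    return DescriptorMatrix(
        values=m.values[:, varying],
        column_map=m.column_map[varying],
        image_shape=m.image_shape,
        removed_columns=removed,
        compound_ids=m.compound_ids,
    )


def center(m: DescriptorMatrix, means: np.ndarray | None = None) -> DescriptorMatrix:
    """Mean-center columns; with ``means`` given (training means), center
    prediction rows consistently with the calibration."""
    if means is None:
        means = m.values.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float)
        if means.shape != (m.n_columns,):
            raise ValueError(
                f"means length {means.shape} does not match {m.n_columns} columns"
            )
    return replace(m, values=m.values - means, column_means=means, centered=True)
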