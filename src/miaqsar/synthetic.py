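"""Synthetic structure-image datasets for exercising the pixel-QSAR pipeline.

Real inputs to this kind of analysis are hand-drawn 2D structure bitmaps of a
congeneric series: a large scaffold shared by every compound, a handful of
localized substituent positions that differ between compounds, and an
activity (here a synthetic first pKa) driven by those substituents.  The
generator reproduces that statistical structure:

* a scaffold of line segments and fused ring perimeters rendered once and
  stamped identically into every image, so scaffold pixels have exactly zero
  variance across compounds;
* a fixed anchor pixel, foreground in every image (the "sulfur atom" used
  for superposition);
* per compound, one binary glyph per substituent region drawn from a seeded
  alphabet of stamps;
* an activity that is linear in the region foreground fractions,
  ``activity_i = sum_r weight_r * frac(i, r) + eps_i`` with
  ``eps_i ~ N(0, noise_sd)``.

Glyph alphabets mimic how substituent drawings actually vary.  Each stamp is
the union of three disjoint layers inside its region box:

* **feature strokes** — a few small cell groups (heteroatom-scale marks)
  whose presence pattern binary-encodes the stamp's *coverage level*; these
  few pixels carry the entire activity signal, the way a single halogen or
  hydroxyl stroke dominates a pKa shift;
* **decoration** — a dense, near-saturated random layer of constant cell
  count redrawn independently for every stamp, emulating the bulk of the
  substituent's ink: high-variance, high-rank, and exactly activity-neutral
  because it never changes the coverage;
* several stamps share each coverage level (*decorative variants* of the
  same substituent), so the descriptor matrix has many more independent
  directions than the activity needs.

The realized foreground fraction of a stamp is exactly affine in its
coverage level, so the activity is a literal linear function of pixels and
noise-free truths are recomputable; at the same time most pixel variance is
activity-neutral, which is the regime in which pixel selection genuinely
pays off over full-image latent-variable regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line, polygon_perimeter

from .imaging import StructureImage

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "write_dataset", "scaffold_mask"]

#: Default workspace mirrors the classical MIA-QSAR geometry: 240 wide x 160
#: tall with the anchor at drawing coordinate (col 110, row 80), i.e. 0-based
#: (row 79, col 109).
DEFAULT_SHAPE = (160, 240)
DEFAULT_ANCHOR = (79, 109)
#: Three 16x16 substituent regions (top, left, bottom, right half-open
#: boxes) kept clear of the default scaffold.
DEFAULT_BOXES = ((20, 38, 36, 54), (20, 180, 36, 196), (120, 110, 136, 126))
#: Per-region activity weights; the middle region is deliberately the most
#: influential.  Weights are large because the coverage differences between
#: substituents are small (see ``fill_range``): a few pixels of ink shift
#: the activity a lot, as a single heteroatom does for a pKa.
DEFAULT_WEIGHTS = (10.0, 13.3, 8.3)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic structure-image generator.

    Region boxes are half-open ``(top, left, bottom, right)`` rectangles in
    0-based pixel coordinates; they must fit inside the image and be disjoint
    from each other and from the scaffold.  ``noise_sd`` is the standard
    deviation of the Gaussian noise added to the linear activity (activity
    units, i.e. pKa units).
    """

    image_height: int = DEFAULT_SHAPE[0]
    image_width: int = DEFAULT_SHAPE[1]
    n_compounds: int = 31
    anchor: tuple[int, int] = DEFAULT_ANCHOR
    region_boxes: tuple[tuple[int, int, int, int], ...] = DEFAULT_BOXES
    region_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    glyph_alphabet_size: int = 24
    coverage_levels: int = 4
    fill_range: tuple[float, float] = (0.82, 0.94)
    noise_sd: float = 0.05
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return len(self.region_boxes)

    def validate(self) -> None:
        h, w = self.image_height, self.image_width
        if self.n_compounds < 2:
            raise ConfigurationError("n_compounds must be at least 2")
        if self.glyph_alphabet_size < 2:
            raise ConfigurationError("glyph_alphabet_size must be at least 2")
        if not 2 <= self.coverage_levels <= self.glyph_alphabet_size:
            raise ConfigurationError("coverage_levels must be in [2, glyph_alphabet_size]")
        if self.glyph_alphabet_size % self.coverage_levels != 0:
            raise ConfigurationError(
                "glyph_alphabet_size must be a multiple of coverage_levels "
                "(stamps are coverage levels x decorative variants)"
            )
        lo, hi = self.fill_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigurationError("fill_range must satisfy 0 <= low < high <= 1")
        if len(self.region_weights) != self.n_regions:
            raise ConfigurationError("one weight per region box is required")
        r, c = self.anchor
        if not (0 <= r < h and 0 <= c < w):
            raise ConfigurationError(f"anchor {self.anchor} outside {h}x{w} image")
        occupancy = np.zeros((h, w), dtype=bool)
        for box in self.region_boxes:
            top, left, bottom, right = box
            if not (0 <= top < bottom <= h and 0 <= left < right <= w):
                raise ConfigurationError(f"region box {box} does not fit inside the image")
            if occupancy[top:bottom, left:right].any():
                raise ConfigurationError(f"region box {box} overlaps another region")
            occupancy[top:bottom, left:right] = True
            area = (bottom - top) * (right - left)
            feature, base = _layer_sizes(area, self.coverage_levels, self.fill_range)
            if feature + base > area:
                raise ConfigurationError(
                    f"region box {box}: feature strokes plus base fill exceed the box; "
                    "shrink fill_range or coverage_levels"
                )
        if (occupancy & scaffold_mask(h, w, self.anchor)).any():
            raise ConfigurationError("region boxes must be disjoint from the scaffold")


@dataclass
class SyntheticDataset:
    """Generated images, activities, and the ground truth behind them.

    ``truth`` records region boxes, weights, glyph fill fractions, the
    per-compound glyph assignments and realized region fractions, and the
    noise draws — enough to recompute every noise-free activity exactly.
    """

    images: list[StructureImage]
    activities: np.ndarray
    truth: dict
    config: GeneratorConfig = field(repr=False, default_factory=GeneratorConfig)

    def noise_free_activities(self) -> np.ndarray:
        """Recompute activities from the truth record, without noise."""
        fractions = np.asarray(self.truth["fractions"], dtype=float)
        weights = np.asarray(self.truth["weights"], dtype=float)
        return fractions @ weights


def scaffold_mask(height: int, width: int, anchor: tuple[int, int]) -> np.ndarray:
    """Render the shared scaffold: a fused six- plus four-membered ring
    system hung from the anchor pixel, with two exocyclic bonds.

    The geometry is a fixed function of (height, width, anchor) so every
    image in a dataset shares bit-identical scaffold pixels.
    """
    mask = np.zeros((height, width), dtype=bool)
    r0, c0 = anchor
    shape = mask.shape

    def _clip(dr: int, dc: int) -> tuple[int, int]:
        return (int(np.clip(r0 + dr, 0, height - 1)), int(np.clip(c0 + dc, 0, width - 1)))

    # six-membered ring with the anchor at its top vertex
    hexagon = [(0, 0), (10, 12), (24, 12), (34, 0), (24, -12), (10, -12)]
    pts = [_clip(dr, dc) for dr, dc in hexagon]
    rr, cc = polygon_perimeter([p[0] for p in pts], [p[1] for p in pts], shape=shape)
    mask[rr, cc] = True
    # fused four-membered ring sharing the hexagon's left edge
    square = [(10, -12), (24, -12), (24, -34), (10, -34)]
    pts = [_clip(dr, dc) for dr, dc in square]
    rr, cc = polygon_perimeter([p[0] for p in pts], [p[1] for p in pts], shape=shape)
    mask[rr, cc] = True
    # exocyclic bonds: up-left from the square, right from the hexagon
    for (dr1, dc1), (dr2, dc2) in [((10, -34), (-4, -50)), ((17, 12), (12, 40))]:
        (ra, ca), (rb, cb) = _clip(dr1, dc1), _clip(dr2, dc2)
        rr, cc = line(ra, ca, rb, cb)
        mask[rr, cc] = True
    mask[r0, c0] = True
    return mask


def _layer_sizes(area: int, levels: int, fill_range: tuple[float, float]) -> tuple[int, int]:
    """Cell budget of the two structured layers in a box of ``area`` cells:
    total feature-stroke cells and the constant decoration count."""
    lo, hi = fill_range
    unit = max(1, round((hi - lo) * area / (levels - 1)))
    n_bits = max(1, int(np.ceil(np.log2(levels))))
    feature = unit * (2**n_bits - 1)
    base = round(lo * area)
    return feature, base


def _glyph_alphabet(
    rng: np.random.Generator,
    box: tuple[int, int, int, int],
    size: int,
    levels: int,
    fill_range: tuple[float, float],
) -> np.ndarray:
    """Binary stamps for one region: ``size`` = ``levels`` coverage levels
    times ``size // levels`` decorative variants.

    Stamp layout (disjoint cell sets drawn once per region from the seeded
    stream):

    * ``n_bits = ceil(log2(levels))`` feature-stroke groups with
      ``unit * 2**j`` cells each; stamp of level ``l`` turns on group j iff
      bit j of l is set, so the stroke cell count is exactly ``unit * l``;
    * a decoration of exactly ``round(lo * area)`` cells, redrawn
      independently for every stamp from the remaining pool.

    Every stamp of level l therefore has exactly
    ``round(lo*area) + unit*l`` foreground cells: the realized fill fraction
    is affine in the coverage level, while decorations vary freely without
    ever touching the coverage.
    """
    top, left, bottom, right = box
    h, w = bottom - top, right - left
    area = h * w
    lo, hi = fill_range
    unit = max(1, round((hi - lo) * area / (levels - 1)))
    n_bits = max(1, int(np.ceil(np.log2(levels))))
    base = round(lo * area)

    order = rng.permutation(area)
    groups, pos = [], 0
    for j in range(n_bits):
        groups.append(order[pos : pos + unit * 2**j])
        pos += unit * 2**j
    pool = order[pos:]
    if base > pool.size:
        raise ConfigurationError(
            f"region box {box}: base fill {base} exceeds the {pool.size}-cell "
            "pool left after feature strokes"
        )

    stamps = np.zeros((size, h, w), dtype=np.uint8)
    for g in range(size):
        level = g % levels
        flat = stamps[g].reshape(-1)
        for j in range(n_bits):
            if (level >> j) & 1:
                flat[groups[j]] = 1
        if base > 0:
            flat[rng.permutation(pool)[:base]] = 1
    return stamps


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a reproducible synthetic dataset under ``config``.

    The scaffold is rendered once and reused; per compound, one glyph per
    region is stamped in, and the activity is the weighted sum of region
    foreground fractions plus Gaussian noise.
    """
    config.validate()
    h, w = config.image_height, config.image_width
    rng = np.random.default_rng(config.seed)

    base = scaffold_mask(h, w, config.anchor).astype(np.uint8)
    alphabets = [
        _glyph_alphabet(
            rng, box, config.glyph_alphabet_size, config.coverage_levels, config.fill_range
        )
        for box in config.region_boxes
    ]
    assignments = rng.integers(0, config.glyph_alphabet_size, size=(config.n_compounds, config.n_regions))
    noise = (
        rng.normal(0.0, config.noise_sd, size=config.n_compounds)
        if config.noise_sd > 0
        else np.zeros(config.n_compounds)
    )

    weights = np.asarray(config.region_weights, dtype=float)
    images: list[StructureImage] = []
    fractions = np.zeros((config.n_compounds, config.n_regions))
    for i in range(config.n_compounds):
        pixels = base.copy()
        for r, box in enumerate(config.region_boxes):
            top, left, bottom, right = box
            stamp = alphabets[r][assignments[i, r]]
            pixels[top:bottom, left:right] = stamp
            fractions[i, r] = stamp.mean()
        images.append(
            StructureImage(pixels=pixels, anchor=config.anchor, compound_id=f"C{i + 1:03d}")
        )
    activities = fractions @ weights + noise

    truth = {
        "weights": weights.tolist(),
        "region_boxes": [list(b) for b in config.region_boxes],
        "glyph_fractions": [a.reshape(a.shape[0], -1).mean(axis=1).tolist() for a in alphabets],
        "assignments": assignments.tolist(),
        "fractions": fractions.tolist(),
        "noise": noise.tolist(),
        "anchor": list(config.anchor),
        "seed": config.seed,
    }
    return SyntheticDataset(images=images, activities=activities, truth=truth, config=config)


def write_dataset(
    ds: SyntheticDataset, directory: str | Path, overwrite: bool = False
) -> pd.DataFrame:
    """Write one PNG per compound (foreground = max intensity) plus
    ``activities.csv``, ``anchors.csv`` (1-based, width-first drawing
    coordinates) and ``truth.json``; returns (and writes) the manifest."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True to replace it")
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for im, activity in zip(ds.images, ds.activities):
        fname = f"{im.compound_id}.png"
        Image.fromarray((im.pixels * 255).astype(np.uint8), mode="L").save(directory / fname)
        rows.append({"compound_id": im.compound_id, "image": fname, "activity": activity})
    manifest = pd.DataFrame(rows)
    manifest[["compound_id", "activity"]].to_csv(directory / "activities.csv", index=False)
    anchors = pd.DataFrame(
        {
            "compound_id": [im.compound_id for im in ds.images],
            "anchor_col": [im.anchor[1] + 1 for im in ds.images],
            "anchor_row": [im.anchor[0] + 1 for im in ds.images],
        }
    )
    anchors.to_csv(directory / "anchors.csv", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
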