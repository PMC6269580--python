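"""Successive projections algorithm (SPA) for pixel-column selection.

SPA builds, from every admissible starting column, a *chain* of columns with
minimal collinearity: at each step every unselected column vector is
projected onto the orthogonal complement of the span of the chain so far,
and the column with the largest projected norm is appended.  Candidate
subsets (the first N columns of each chain, for N in a configured range) are
then scored by the root-mean-square error of a multiple linear regression on
an independent validation set, and the best-scoring (start, N) wins.

The regression scorer is the classical SPA formulation (ordinary MLR); the
final reported calibration refits PLS on the winning columns — see
:mod:`miaqsar.modeling`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionResult", "build_chain", "spa_select"]

#: Columns whose norm is below this are excluded as chain starts.
MIN_START_NORM = 1e-12


@dataclass
class SelectionResult:
    """Winning SPA subset plus the full chain and score tables."""

    selected_columns: list[int]
    chain_table: dict[int, list[int]]
    score_table: dict[tuple[int, int], float]
    winning_start: int
    winning_score: float

    @property
    def n_selected(self) -> int:
        return len(self.selected_columns)


def _as_array(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def build_chain(x_train, start_column: int, max_len: int) -> list[int]:
    """Forward projection chain of column indices, beginning at
    ``start_column``.

    The chain stops early (with a warning) if every remaining column lies in
    the span of the chain, i.e. ``max_len`` exceeds the effective rank.
    """
    x = _as_array(x_train)
    n, p = x.shape
    if not 0 <= start_column < p:
        raise ValueError(f"start column {start_column} out of range for {p} columns")
    norms0 = np.linalg.norm(x, axis=0)
    if norms0[start_column] < MIN_START_NORM:
        raise ValueError(f"start column {start_column} has (near-)zero norm")
    if max_len < 1:
        raise ValueError("max_len must be at least 1")

    tol = 1e-10 * norms0.max()
    chain = [start_column]
    resid = x.copy()
    for _ in range(1, max_len):
        # deflate by the newest chain vector's residual direction; chain
        # vectors end up sequentially orthogonalized (Gram-Schmidt).
        v = resid[:, chain[-1]]
        q = v / np.linalg.norm(v)
        resid = resid - np.outer(q, q @ resid)
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))  # ties -> lowest column index
        if norms[nxt] <= tol:
            warnings.warn(
                f"chain from column {start_column} truncated at length "
                f"{len(chain)}: remaining columns are linearly dependent",
                stacklevel=2,
            )
            break
        chain.append(nxt)
    return chain


def _mlr_rmse(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cols: list[int],
) -> float:
    """Validation RMSE of an intercept-included MLR on ``cols``; singular
    designs score +inf."""
    a = np.column_stack([np.ones(len(y_train)), x_train[:, cols]])
    coef, _, rank, _ = np.linalg.lstsq(a, y_train, rcond=None)
    if rank < a.shape[1]:
        return np.inf
    pred = np.column_stack([np.ones(len(y_val)), x_val[:, cols]]) @ coef
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


def spa_select(
    x_train,
    y_train,
    x_val,
    y_val,
    n_min: int = 2,
    n_max: int | None = None,
) -> SelectionResult:
    """Run SPA over every admissible start and every cardinality in
    ``[n_min, n_max]``, scoring candidates on ``(x_val, y_val)``.

    Ties in the winning score go to the smallest N, then the smallest start
    index (parsimony, determinism).
    """
    xt = _as_array(x_train)
    xv = _as_array(x_val)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n, p = xt.shape
    if xv.shape[0] == 0:
        raise ValueError("SPA scoring requires a non-empty validation set")
    if xv.shape[1] != p:
        raise ValueError("training and validation matrices must share columns")
    if n_max is None:
        n_max = min(20, n - 1, p)
    if not 1 <= n_min <= n_max:
        raise ValueError(f"need 1 <= n_min <= n_max, got [{n_min}, {n_max}]")
    if n_max > min(n - 1, p):
        raise ValueError(f"n_max {n_max} exceeds min(n_train - 1, n_columns) = {min(n - 1, p)}")

    norms = np.linalg.norm(xt, axis=0)
    starts = [j for j in range(p) if norms[j] >= MIN_START_NORM]
    if not starts:
        raise ValueError("no column has non-zero norm")

    # build every chain; truncation at the matrix rank is routine here, so
    # the per-chain warnings are summarized into one
    chain_table: dict[int, list[int]] = {}
    n_truncated = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s in starts:
            chain_table[s] = build_chain(xt, s, n_max)
            if len(chain_table[s]) < n_max:
                n_truncated += 1
    if n_truncated:
        warnings.warn(
            f"{n_truncated} of {len(starts)} chains truncated below {n_max} "
            "columns (matrix rank limit)",
            stacklevel=2,
        )
    score_table: dict[tuple[int, int], float] = {}
    best: tuple[float, int, int] | None = None  # (score, N, start)
    for n_sel in range(n_min, n_max + 1):
        for s in starts:
            chain = chain_table[s]
            if len(chain) < n_sel:
                continue
            score = _mlr_rmse(xt, y_train, xv, y_val, chain[:n_sel])
            score_table[(s, n_sel)] = score
            if best is None or score < best[0]:
                best = (score, n_sel, s)
    if best is None or not np.isfinite(best[0]):
        raise ValueError("no candidate subset could be scored (all regressions singular)")

    score, n_sel, start = best
    return SelectionResult(
        selected_columns=chain_table[start][:n_sel],
        chain_table=chain_table,
        score_table=score_table,
        winning_start=start,
        winning_score=score,
    )


def overlay_selection(
    mean_image: np.ndarray, coords: np.ndarray, halo: int = 1
) -> np.ndarray:
    """RGB rendering of selected pixels (red, with a small halo for
    visibility) over the mean structure image (grayscale)."""
    g = (np.asarray(mean_image, dtype=float) * 255).clip(0, 255).astype(np.uint8)
    rgb = np.stack([g, g, g], axis=-1)
    h, w = g.shape
    for r, c in np.asarray(coords, dtype=int):
        rr = slice(max(0, r - halo), min(h, r + halo + 1))
        cc = slice(max(0, c - halo), min(w, c + halo + 1))
        rgb[rr, cc] = (255, 0, 0)
    return rgb
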