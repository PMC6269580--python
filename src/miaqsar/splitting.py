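"""Kennard-Stone maximin selection of a representative training set.

The algorithm is the classical deterministic one: seed with the two samples
farthest apart (Euclidean), then repeatedly add the unselected sample whose
minimum distance to the already-selected set is largest.  The remainder forms
the prediction set.  Distances are computed on the matrix as given —
mean-centering is a rigid translation and leaves them unchanged, as does
dropping columns that are constant across samples.

Ties are broken toward the lowest row index (and, for the initial pair, the
lexicographically smallest index pair), so the split is reproducible without
any seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitAssignment", "kennard_stone"]


@dataclass
class SplitAssignment:
    """Ordered Kennard-Stone training indices plus the leftover prediction set."""

    training_indices: list[int]
    prediction_indices: list[int]

    @property
    def n_train(self) -> int:
        return len(self.training_indices)

    def to_frame(self, compound_ids: list[str] | None = None) -> pd.DataFrame:
        n = self.n_train + len(self.prediction_indices)
        ids = compound_ids if compound_ids is not None else [str(i) for i in range(n)]
        rank = {idx: k + 1 for k, idx in enumerate(self.training_indices)}
        rows = [
            {
                "compound_id": ids[i],
                "role": "training" if i in rank else "prediction",
                "selection_rank": rank.get(i, ""),
            }
            for i in range(n)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, compound_ids: list[str] | None = None) -> None:
        self.to_frame(compound_ids).to_csv(path, index=False)


def kennard_stone(x, n_train: int) -> SplitAssignment:
    """Split rows of ``x`` (array or DescriptorMatrix) into an ordered
    ``n_train``-sample training set and the remaining prediction set."""
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("x must be a 2D matrix with at least one column")
    n = values.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be between 2 and {n}, got {n_train}")

    d = squareform(pdist(values, metric="euclidean"))

    # initial pair: globally farthest apart; ties -> lexicographically
    # smallest (i, j).  np.argmax on the upper triangle scans in that order.
    iu, ju = np.triu_indices(n, k=1)
    best = np.argmax(d[iu, ju])
    selected = [int(iu[best]), int(ju[best])]
    remaining = [i for i in range(n) if i not in selected]

    min_dist = d[:, selected].min(axis=1)
    while len(selected) < n_train:
        rem = np.array(remaining)
        nxt = int(rem[np.argmax(min_dist[rem])])  # argmax keeps lowest index on ties
        selected.append(nxt)
        remaining.remove(nxt)
        min_dist = np.minimum(min_dist, d[:, nxt])

    return SplitAssignment(training_indices=selected, prediction_indices=remaining)
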