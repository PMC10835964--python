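"""Kennard-Stone selection of a calibration subset.

The Kennard-Stone algorithm picks a calibration set that spans spectral
space: it seeds with the two most distant samples (Euclidean distance) and
then repeatedly adds the candidate whose minimum distance to the already
selected set is largest (greedy max-min).  The remainder forms the
validation set.  The procedure is fully deterministic; ties are broken
toward the smaller original row index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, DegenerateInputError


@dataclass
class SplitResult:
    """Outcome of a calibration/validation split.

    ``calibration_ids`` is in selection order; ``selection_order`` repeats it
    explicitly for serialization clarity.
    """

    fraction: float
    calibration_ids: list
    validation_ids: list
    selection_order: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selection_order:
            self.selection_order = list(self.calibration_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "fraction": self.fraction,
                "calibration_ids": list(self.calibration_ids),
                "validation_ids": list(self.validation_ids),
                "selection_order": list(self.selection_order),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "SplitResult":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        d = json.loads(text)
        return cls(
            fraction=d["fraction"],
            calibration_ids=d["calibration_ids"],
            validation_ids=d["validation_ids"],
            selection_order=d.get("selection_order", []),
        )


class KennardStoneSplitter(BaseEstimator):
    """Deterministic max-min distance splitter.

    Compatible with the scikit-learn cross-validation protocol: ``split``
    yields a single ``(calibration_indices, validation_indices)`` pair.

    Parameters
    ----------
    fraction : float in (0, 1)
        Proportion of samples placed in the calibration set; the target
        count is ``round(fraction * n)`` with round-half-up.
    """

    def __init__(self, fraction: float = 0.5):
        self.fraction = fraction

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1

    def split(self, X, y=None, groups=None):
        res = self.select(X)
        yield (
            np.asarray(res.calibration_ids, dtype=int),
            np.asarray(res.validation_ids, dtype=int),
        )

    def select(self, X, ids: Sequence | None = None) -> SplitResult:
        """Run the selection and return a :class:`SplitResult`.

        ``ids`` relabels rows in the result (defaults to row positions).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if not (0.0 < self.fraction < 1.0):
            raise ConfigurationError("fraction must be in (0, 1)")
        if n < 4:
            raise ConfigurationError("Kennard-Stone needs at least 4 samples")
        n_cal = int(np.floor(self.fraction * n + 0.5))
        if n_cal < 2 or n_cal >= n:
            raise ConfigurationError(
                f"fraction {self.fraction} selects {n_cal} of {n} samples; "
                "need at least 2 selected and 1 held out"
            )

        D = squareform(pdist(X, metric="euclidean"))
        if D.max() == 0.0:
            raise DegenerateInputError("all rows identical: max pairwise distance is 0")

        # seed: lexicographically smallest pair among those at max distance
        i, j = np.unravel_index(int(np.argmax(D)), D.shape)
        if i > j:
            i, j = j, i
        selected = [int(i), int(j)]
        # running min distance of every sample to the selected set;
        # argmax with -inf masking breaks ties toward the smaller index
        min_dist = np.minimum(D[i], D[j])
        min_dist[selected] = -np.inf
        while len(selected) < n_cal:
            k = int(np.argmax(min_dist))
            selected.append(k)
            min_dist = np.minimum(min_dist, D[k])
            min_dist[k] = -np.inf

        ids = list(range(n)) if ids is None else list(ids)
        if len(ids) != n:
            raise ConfigurationError("ids length does not match number of rows")
        in_cal = set(selected)
        return SplitResult(
            fraction=self.fraction,
            calibration_ids=[ids[k] for k in selected],
            validation_ids=[ids[k] for k in range(n) if k not in in_cal],
        )


def kennard_stone_split(X, fraction: float = 0.5, ids: Sequence | None = None) -> SplitResult:
    """Functional wrapper around :class:`KennardStoneSplitter`."""
    return KennardStoneSplitter(fraction=fraction).select(X, ids=ids)
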