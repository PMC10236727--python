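"""Feature-level quality control.

Within an event class, each channel's feature values across trials are
screened with the three-sigma rule (strictly beyond mean +/- 3 sd); flagged
entries are replaced by the same-trial mean over unflagged neighboring
channels.  A Shapiro-Wilk normality screen per channel is reported but does
not trigger exclusion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .encoding import FeatureMatrix

__all__ = [
    "AdjacencyMap",
    "QCReport",
    "ring_adjacency",
    "load_adjacency",
    "detect_outliers_three_sigma",
    "shapiro_wilk_test",
    "impute_from_neighbors",
    "qc_feature_matrix",
]

AdjacencyMap = dict[str, list[str]]


class ImputationError(ValueError):
    """A flagged channel has no unflagged neighbor to impute from."""


@dataclass
class QCReport:
    outlier_mask: np.ndarray            # trial x channel booleans
    normality: dict[str, tuple[float, float]]   # channel -> (W, p)
    n_imputed: int

    def to_dict(self) -> dict:
        return {
            "n_outliers": int(self.outlier_mask.sum()),
            "n_imputed": int(self.n_imputed),
            "outlier_fraction": float(self.outlier_mask.mean()),
            "normality": {ch: {"W": w, "p": p}
                          for ch, (w, p) in self.normality.items()},
        }


def ring_adjacency(channel_ids: list[str]) -> AdjacencyMap:
    """1-D ring neighborhood over channel order (synthetic-montage default)."""
    n = len(channel_ids)
    if n < 2:
        return {c: [] for c in channel_ids}
    adj: AdjacencyMap = {}
    for i, c in enumerate(channel_ids):
        neigh = {channel_ids[(i - 1) % n], channel_ids[(i + 1) % n]} - {c}
        adj[c] = sorted(neigh)
    return adj


def load_adjacency(path: str | Path) -> AdjacencyMap:
    """Read a JSON mapping channel_id -> [neighbor ids]; validates symmetry."""
    adj = json.loads(Path(path).read_text())
    for ch, neighbors in adj.items():
        for nb in neighbors:
            if ch == nb:
                raise ValueError(f"channel {ch} lists itself as a neighbor")
            if ch not in adj.get(nb, []):
                raise ValueError(f"adjacency not symmetric: {ch} -> {nb}")
    return {str(k): [str(v) for v in vs] for k, vs in adj.items()}


def detect_outliers_three_sigma(values: np.ndarray) -> np.ndarray:
    """Flag entries strictly beyond mean +/- 3 standard deviations.

    With zero dispersion nothing is flagged; a value exactly at the boundary
    is kept.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return (values > mean + 3 * sd) | (values < mean - 3 * sd)


def shapiro_wilk_test(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (screening only, 3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float).ravel()
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def impute_from_neighbors(matrix: FeatureMatrix, mask: np.ndarray,
                          adjacency: AdjacencyMap) -> FeatureMatrix:
    """Replace each masked entry with the same-trial mean over unflagged
    neighboring channels; all other entries are untouched."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != matrix.values.shape:
        raise ValueError("mask shape must match the feature matrix")
    values = matrix.values.copy()
    col = {c: j for j, c in enumerate(matrix.channel_ids)}
    for i, j in zip(*np.nonzero(mask)):
        ch = matrix.channel_ids[j]
        donors = [col[nb] for nb in adjacency.get(ch, [])
                  if nb in col and not mask[i, col[nb]]]
        if not donors:
            raise ImputationError(
                f"channel {ch} (trial {matrix.trial_ids[i]}) has no unflagged "
                f"neighbor")
        values[i, j] = matrix.values[i, donors].mean()
    return dataclasses.replace(matrix, values=values,
                               trial_ids=list(matrix.trial_ids),
                               channel_ids=list(matrix.channel_ids))


def qc_feature_matrix(matrix: FeatureMatrix,
                      adjacency: AdjacencyMap | None = None
                      ) -> tuple[FeatureMatrix, QCReport]:
    """Per-channel three-sigma screen across trials (within this event
    class), neighbor-mean imputation, and a normality report."""
    if adjacency is None:
        adjacency = ring_adjacency(matrix.channel_ids)
    m, n = matrix.values.shape
    mask = np.zeros((m, n), dtype=bool)
    normality: dict[str, tuple[float, float]] = {}
    for j, ch in enumerate(matrix.channel_ids):
        column = matrix.values[:, j]
        if m >= 2:
            mask[:, j] = detect_outliers_three_sigma(column)
        if 3 <= m <= 5000 and np.ptp(column) > 0:
            normality[ch] = shapiro_wilk_test(column)
    imputed = impute_from_neighbors(matrix, mask, adjacency)
    report = QCReport(outlier_mask=mask, normality=normality,
                      n_imputed=int(mask.sum()))
    return imputed, report
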