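"""Matrix containers, copy-number rescaling and MDLP discretization.

The selection criteria in this package operate on discrete (integer-coded)
feature matrices.  GISTIC-style copy-number calls {−2,−1,0,1,2} are already
categorical; continuous features are discretized with the Fayyad–Irani
minimum-description-length (MDLP) procedure: recursive binary splitting on
class-boundary midpoints, each split accepted only when its information gain
exceeds the MDL coding cost of announcing the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .infotheory import _entropy_from_counts, mutual_information

__all__ = [
    "FeatureMatrix",
    "DiscreteFeatureMatrix",
    "DiscretizationModel",
    "cnv_rescale",
    "mdlp_cut_points",
    "fit_mdlp",
    "apply_discretization",
]


def _check_matrix(values, feature_ids, labels):
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"values must be 2-D, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        cells = ", ".join(f"(row {r}, col {c})" for r, c in bad[:5])
        raise ValueError(f"matrix contains missing/non-finite values at {cells}")
    feature_ids = list(feature_ids)
    if len(feature_ids) != values.shape[1]:
        raise ValueError("feature_ids length must equal number of columns")
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"duplicate feature ids: {dupes}")
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size != values.shape[0]:
        raise ValueError("labels must be 1-D with one entry per sample")
    return values, feature_ids, labels


@dataclass
class FeatureMatrix:
    """n_samples × n_features real-valued matrix with a categorical label."""

    values: np.ndarray
    feature_ids: List[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values, self.feature_ids, self.labels = _check_matrix(
            self.values, self.feature_ids, self.labels
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


@dataclass
class DiscreteFeatureMatrix:
    """As :class:`FeatureMatrix`, but every column holds integer category codes."""

    values: np.ndarray
    feature_ids: List[str]
    labels: np.ndarray

    def __post_init__(self):
        vals, self.feature_ids, self.labels = _check_matrix(
            self.values, self.feature_ids, self.labels
        )
        cast = vals.astype(np.int64)
        if not np.array_equal(cast, vals):
            raise ValueError("discrete matrix contains non-integer codes")
        self.values = cast
        codes, encoded = np.unique(self.labels, return_inverse=True)
        self.label_codes = encoded.ravel().astype(np.int64)
        self.label_alphabet = codes

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


@dataclass
class DiscretizationModel:
    """Per-feature strictly-increasing cut points; bin = #cuts below the value."""

    cuts: Dict[str, List[float]] = field(default_factory=dict)

    def __post_init__(self):
        for fid, c in self.cuts.items():
            arr = list(c)
            if any(b <= a for a, b in zip(arr, arr[1:])):
                raise ValueError(f"cut points for {fid!r} must be strictly increasing")
            self.cuts[fid] = arr

    def transform_column(self, feature_id: str, x: np.ndarray) -> np.ndarray:
        cuts = self.cuts[feature_id]
        return np.searchsorted(np.asarray(cuts, dtype=float), x, side="left").astype(
            np.int64
        )


def cnv_rescale(m: FeatureMatrix) -> FeatureMatrix:
    """Divide every value by the global maximum absolute value, into [−1, 1].

    An all-zero matrix is returned unchanged (with a warning) to avoid a
    division by zero.  The rescale is monotone and affine per matrix, so it
    never changes entropies of the induced categories; it matters only for
    classifiers consuming numeric inputs.
    """
    max_abs = float(np.max(np.abs(m.values))) if m.values.size else 0.0
    if max_abs == 0.0:
        warnings.warn("matrix is all zeros; returning it unchanged", stacklevel=2)
        return FeatureMatrix(m.values.copy(), list(m.feature_ids), m.labels.copy())
    return FeatureMatrix(m.values / max_abs, list(m.feature_ids), m.labels.copy())


def _class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(labels, minlength=n_classes)


def _mdlp_recurse(
    order_x: np.ndarray, order_y: np.ndarray, n_classes: int, cuts: List[float]
) -> None:
    """Recursively split sorted (x, label) pairs, keeping MDL-accepted cuts."""
    n = order_x.size
    if n < 2:
        return
    total_counts = _class_counts(order_y, n_classes)
    h_s = _entropy_from_counts(total_counts)
    if h_s == 0.0:
        return

    # Candidate boundaries: midpoints between consecutive distinct x values.
    # Restricting to points where the class composition changes is the
    # standard boundary-point optimization and never discards an optimal cut.
    distinct_end = np.nonzero(np.diff(order_x) > 0)[0]  # index i: cut between i, i+1
    if distinct_end.size == 0:
        return

    left_counts = np.cumsum(
        np.eye(n_classes, dtype=np.int64)[order_y], axis=0
    )  # n × n_classes prefix class counts
    best = None
    for i in distinct_end:
        left = left_counts[i]
        right = total_counts - left
        h_left = _entropy_from_counts(left)
        h_right = _entropy_from_counts(right)
        n_left = int(left.sum())
        weighted = (n_left * h_left + (n - n_left) * h_right) / n
        cut_value = (order_x[i] + order_x[i + 1]) / 2.0
        # strict < keeps the smallest cut value on exact gain ties
        if best is None or weighted < best[0] - 1e-15:
            best = (weighted, cut_value, i, left, right, h_left, h_right)

    weighted, cut_value, i, left, right, h_left, h_right = best
    gain = h_s - weighted
    k = int(np.count_nonzero(total_counts))
    k1 = int(np.count_nonzero(left))
    k2 = int(np.count_nonzero(right))
    delta = np.log2(3.0**k - 2.0) - (k * h_s - k1 * h_left - k2 * h_right)
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return

    cuts.append(float(cut_value))
    _mdlp_recurse(order_x[: i + 1], order_y[: i + 1], n_classes, cuts)
    _mdlp_recurse(order_x[i + 1 :], order_y[i + 1 :], n_classes, cuts)


def mdlp_cut_points(x: Sequence[float], labels: Sequence[int]) -> List[float]:
    """Fayyad–Irani MDLP cut points for one continuous column.

    Splits are chosen to maximize class-information gain among midpoints
    between consecutive distinct values, and kept only when
    ``Gain > [log2(N−1) + log2(3^k − 2) − (k·H(S) − k1·H(S1) − k2·H(S2))] / N``
    on the segment being split.  Recursion applies the same test at every
    level; gain ties resolve to the smaller cut value (the first candidate in
    sorted order).  A constant column yields no cuts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and labels must be equal-length 1-D sequences")
    if x.size == 0:
        raise ValueError("empty column")
    _, y_codes = np.unique(y, return_inverse=True)
    y_codes = y_codes.ravel()
    n_classes = int(y_codes.max()) + 1
    order = np.argsort(x, kind="stable")
    cuts: List[float] = []
    _mdlp_recurse(x[order], y_codes[order], n_classes, cuts)
    return sorted(cuts)


def fit_mdlp(m: FeatureMatrix) -> DiscretizationModel:
    """Fit MDLP cut points for every feature column against the class label."""
    _, y_codes = np.unique(m.labels, return_inverse=True)
    if np.unique(y_codes).size < 2:
        raise ValueError("labels must have at least two classes for MDLP")
    return DiscretizationModel(
        {fid: mdlp_cut_points(m.values[:, j], y_codes) for j, fid in enumerate(m.feature_ids)}
    )


def apply_discretization(
    m: FeatureMatrix, model: DiscretizationModel
) -> DiscreteFeatureMatrix:
    """Map every value to its bin index under the fitted model."""
    missing = [fid for fid in m.feature_ids if fid not in model.cuts]
    if missing:
        raise KeyError(f"discretization model lacks cut points for: {missing}")
    binned = np.column_stack(
        [
            model.transform_column(fid, m.values[:, j])
            for j, fid in enumerate(m.feature_ids)
        ]
    )
    return DiscreteFeatureMatrix(binned, list(m.feature_ids), m.labels.copy())


def identity_discretization(m: FeatureMatrix) -> DiscreteFeatureMatrix:
    """Treat an already-discrete matrix (e.g. GISTIC codes) as categorical.

    Each column's distinct values are mapped to consecutive codes; raises if a
    column holds non-integer values.
    """
    cols = []
    for j in range(m.n_features):
        col = m.values[:, j]
        if not np.array_equal(col.astype(np.int64), col):
            raise ValueError(
                f"column {m.feature_ids[j]!r} is not integer-coded; discretize it first"
            )
        _, codes = np.unique(col, return_inverse=True)
        cols.append(codes.ravel())
    return DiscreteFeatureMatrix(
        np.column_stack(cols), list(m.feature_ids), m.labels.copy()
    )


def mi_with_labels(m: DiscreteFeatureMatrix, feature_id: str) -> float:
    """Convenience: plug-in MI between one discrete column and the labels."""
    return mutual_information(m.column(feature_id), m.label_codes)
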