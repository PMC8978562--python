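"""Plug-in (empirical-frequency) estimators of discrete information measures.

All measures operate on integer-coded categorical sample vectors of a common
length and are reported in bits (log base 2, with the convention 0·log 0 = 0).
Joint quantities are estimated by exact row-tuple counting, which is the
natural estimator once the data have been discretized: every distinct
combination of category codes across the supplied vectors is one outcome of
the joint distribution.

The multivariate dependence measure :func:`total_correlation` (sum of marginal
entropies minus the joint entropy) generalizes mutual information to any
number of variables; for discrete variables it equals the negative copula
entropy, which :func:`copula_entropy` exposes directly.  Tiny negative values
produced by floating-point cancellation are clamped to zero (threshold 1e-12).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "joint_mutual_information",
    "interaction_gain",
    "symmetrical_uncertainty",
    "total_correlation",
    "copula_entropy",
]

_NEG_TOL = 1e-12


def _as_codes(x: Sequence[int] | np.ndarray, name: str = "vector") -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one observation")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
        cast = arr.astype(np.int64)
        if np.issubdtype(arr.dtype, np.floating) and not np.array_equal(cast, arr):
            raise ValueError(f"{name} contains non-integer category codes")
        arr = cast
    return arr


def _check_equal_lengths(arrs: Sequence[np.ndarray]) -> int:
    n = arrs[0].size
    for a in arrs[1:]:
        if a.size != n:
            raise ValueError(
                f"all vectors must have equal length; got {n} and {a.size}"
            )
    return n


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p @ np.log2(p)))


def _clamp(value: float) -> float:
    if -_NEG_TOL < value < 0.0:
        return 0.0
    return value


def joint_codes(xs: Sequence[np.ndarray]) -> np.ndarray:
    """Collapse a list of equal-length code vectors into one code per row.

    Rows with identical tuples across ``xs`` receive identical codes.  Used
    both here and by the selection engine to extend a cached joint code with
    one more column at O(n log n) cost.
    """
    stacked = np.column_stack([_as_codes(x) for x in xs])
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes.ravel()


def entropy(x: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy H(X) in bits of one categorical sample vector."""
    arr = _as_codes(x)
    _, counts = np.unique(arr, return_counts=True)
    return _entropy_from_counts(counts)


def joint_entropy(xs: Sequence[Sequence[int] | np.ndarray]) -> float:
    """Joint entropy H(X1,...,Xq) of the row-tuple distribution."""
    if len(xs) == 0:
        raise ValueError("joint_entropy requires at least one vector")
    arrs = [_as_codes(x, f"vector {i}") for i, x in enumerate(xs)]
    _check_equal_lengths(arrs)
    if len(arrs) == 1:
        return entropy(arrs[0])
    codes = joint_codes(arrs)
    _, counts = np.unique(codes, return_counts=True)
    return _entropy_from_counts(counts)


def conditional_entropy(y, x) -> float:
    """H(Y|X) = H(X,Y) − H(X); non-negative for plug-in estimates."""
    ya, xa = _as_codes(y, "y"), _as_codes(x, "x")
    _check_equal_lengths([ya, xa])
    return max(joint_entropy([xa, ya]) - entropy(xa), 0.0)


def mutual_information(x, y) -> float:
    """I(X;Y) = H(X) + H(Y) − H(X,Y), clamped at zero from below."""
    xa, ya = _as_codes(x, "x"), _as_codes(y, "y")
    _check_equal_lengths([xa, ya])
    return _clamp(entropy(xa) + entropy(ya) - joint_entropy([xa, ya]))


def conditional_mutual_information(x, y, z) -> float:
    """I(X;Y|Z) = H(Y|Z) − H(Y|X,Z)."""
    xa, ya, za = _as_codes(x, "x"), _as_codes(y, "y"), _as_codes(z, "z")
    _check_equal_lengths([xa, ya, za])
    h_yz = joint_entropy([za, ya]) - entropy(za)
    h_y_xz = joint_entropy([xa, za, ya]) - joint_entropy([xa, za])
    return _clamp(h_yz - h_y_xz)


def joint_mutual_information(xs, y) -> float:
    """I(X1..Xq;Y) via H(X1..Xq) + H(Y) − H(X1..Xq,Y)."""
    if len(xs) == 0:
        raise ValueError("joint_mutual_information requires >= 1 predictor")
    arrs = [_as_codes(x, f"vector {i}") for i, x in enumerate(xs)]
    ya = _as_codes(y, "y")
    _check_equal_lengths(arrs + [ya])
    return _clamp(joint_entropy(arrs) + entropy(ya) - joint_entropy(arrs + [ya]))


def interaction_gain(x, y, z) -> float:
    """Three-way interaction information I(X;Y;Z) = I(X,Y;Z) − I(X;Z) − I(Y;Z).

    Positive values indicate synergy (the pair carries information about Z that
    neither member carries alone); negative values indicate redundancy.
    """
    xa, ya, za = _as_codes(x, "x"), _as_codes(y, "y"), _as_codes(z, "z")
    _check_equal_lengths([xa, ya, za])
    return (
        joint_mutual_information([xa, ya], za)
        - mutual_information(xa, za)
        - mutual_information(ya, za)
    )


def symmetrical_uncertainty(x, y) -> float:
    """SU(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) in [0, 1]; 0 if both are constant."""
    xa, ya = _as_codes(x, "x"), _as_codes(y, "y")
    _check_equal_lengths([xa, ya])
    hx, hy = entropy(xa), entropy(ya)
    denom = hx + hy
    if denom <= _NEG_TOL:
        return 0.0
    su = 2.0 * _clamp(hx + hy - joint_entropy([xa, ya])) / denom
    return min(max(su, 0.0), 1.0)


def total_correlation(xs) -> float:
    """Multivariate mutual information: Σ H(X_i) − H(X_1,...,X_q), q ≥ 2."""
    if len(xs) < 2:
        raise ValueError("total_correlation requires at least 2 vectors")
    arrs = [_as_codes(x, f"vector {i}") for i, x in enumerate(xs)]
    _check_equal_lengths(arrs)
    return _clamp(sum(entropy(a) for a in arrs) - joint_entropy(arrs))


def copula_entropy(xs) -> float:
    """Discrete copula entropy: the negative of :func:`total_correlation`.

    For discrete variables the multivariate mutual information equals the
    negative copula entropy, so this is computed by entropy decomposition
    rather than by integrating a copula density.
    """
    return -total_correlation(xs)
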