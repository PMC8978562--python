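"""Independent oracles used by the test-suite.

Two families:

* :class:`TableDist` — a joint probability table over a few categorical
  variables, with every information measure computed by direct summation of
  p·log p terms over the table (no sample-based estimation).  Realizing the
  table as an exact sample (counts proportional to probabilities) lets the
  plug-in estimators be checked against closed-form summation.

* Reference greedy selection — a from-scratch re-implementation of every
  criterion's scoring rule and weight update, built only on the public
  information-measure functions applied to raw columns, with no caching and
  no incremental joint codes.  The production engines must match it round by
  round, including the lowest-column-index tie rule.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

from criafs.infotheory import (
    entropy,
    interaction_gain,
    joint_entropy,
    joint_mutual_information,
    mutual_information,
    symmetrical_uncertainty,
    total_correlation,
)


def _xlog2x(p: float) -> float:
    return 0.0 if p == 0.0 else p * math.log2(p)


class TableDist:
    """Joint pmf over q categorical variables, indexed 0..q−1."""

    def __init__(self, outcomes: Sequence[Tuple[int, ...]], probs: Sequence[float]):
        self.outcomes = [tuple(o) for o in outcomes]
        self.probs = [float(p) for p in probs]
        assert abs(sum(self.probs) - 1.0) < 1e-12
        assert all(p >= 0 for p in self.probs)
        self.q = len(self.outcomes[0])

    @classmethod
    def from_counts(cls, counts: Dict[Tuple[int, ...], int]) -> "TableDist":
        total = sum(counts.values())
        items = sorted(counts.items())
        dist = cls([o for o, _ in items], [c / total for _, c in items])
        dist._counts = [c for _, c in items]
        return dist

    def marginal(self, axes: Sequence[int]) -> Dict[Tuple[int, ...], float]:
        out: Dict[Tuple[int, ...], float] = {}
        for o, p in zip(self.outcomes, self.probs):
            key = tuple(o[a] for a in axes)
            out[key] = out.get(key, 0.0) + p
        return out

    def entropy(self, axes: Sequence[int]) -> float:
        return -sum(_xlog2x(p) for p in self.marginal(axes).values())

    def mi(self, a: int, b: int) -> float:
        return self.entropy([a]) + self.entropy([b]) - self.entropy([a, b])

    def cmi(self, a: int, b: int, z: int) -> float:
        # I(A;B|Z) = H(A,Z) + H(B,Z) − H(A,B,Z) − H(Z)
        return (
            self.entropy([a, z])
            + self.entropy([b, z])
            - self.entropy([a, b, z])
            - self.entropy([z])
        )

    def jmi(self, xs: Sequence[int], y: int) -> float:
        xs = list(xs)
        return self.entropy(xs) + self.entropy([y]) - self.entropy(xs + [y])

    def ig(self, a: int, b: int, z: int) -> float:
        return self.jmi([a, b], z) - self.mi(a, z) - self.mi(b, z)

    def su(self, a: int, b: int) -> float:
        denom = self.entropy([a]) + self.entropy([b])
        return 0.0 if denom == 0 else 2.0 * self.mi(a, b) / denom

    def total_correlation(self, axes: Sequence[int]) -> float:
        return sum(self.entropy([a]) for a in axes) - self.entropy(list(axes))

    def exact_sample(self, multiplier: int = 1) -> List[np.ndarray]:
        """Realize the pmf as columns of a sample whose empirical frequencies
        equal the probabilities exactly (tables built via :meth:`from_counts`
        keep their integer counts)."""
        rows: List[Tuple[int, ...]] = []
        for o, count in zip(self.outcomes, self._counts):
            rows.extend([o] * (count * multiplier))
        arr = np.array(rows, dtype=np.int64)
        return [arr[:, j].copy() for j in range(self.q)]


def random_count_table(
    rng: np.random.Generator, n_vars: int, n_cats: int, max_count: int = 4
) -> TableDist:
    """A random joint distribution with small integer counts over the full
    outcome grid (zero counts allowed, at least two distinct outcomes)."""
    while True:
        grid = list(itertools.product(range(n_cats), repeat=n_vars))
        counts = {o: int(rng.integers(0, max_count + 1)) for o in grid}
        counts = {o: c for o, c in counts.items() if c > 0}
        if len(counts) >= 2:
            return TableDist.from_counts(counts)


# ---------------------------------------------------------------------------
# reference greedy selection (no caching, no incremental state)
# ---------------------------------------------------------------------------


def reference_cria_score(
    cols: List[np.ndarray], c: np.ndarray, selected: List[int], f: int
) -> float:
    rel = symmetrical_uncertainty(cols[f], c)
    red = sum(symmetrical_uncertainty(cols[f], cols[s]) for s in selected) / len(
        selected
    )
    tc_den = total_correlation([cols[s] for s in selected] + [c])
    if tc_den <= 1e-12:
        if_cria = 1.0
    else:
        tc_num = total_correlation([cols[s] for s in selected] + [cols[f], c])
        if_cria = tc_num / tc_den
    return (rel - red) * if_cria


def reference_cria_score_expanded(
    cols: List[np.ndarray], c: np.ndarray, selected: List[int], f: int
) -> float:
    """The fully expanded entropy form of the CRIA criterion: the interaction
    factor written as [ΣH(f_k) + H(f) + H(c) − H(Ω,f,c)] / [ΣH(f_k) + H(c)
    − H(Ω,c)]."""
    rel = symmetrical_uncertainty(cols[f], c)
    red = sum(symmetrical_uncertainty(cols[f], cols[s]) for s in selected) / len(
        selected
    )
    sum_h = sum(entropy(cols[s]) for s in selected)
    den = sum_h + entropy(c) - joint_entropy([cols[s] for s in selected] + [c])
    if den <= 1e-12:
        ratio = 1.0
    else:
        num = (
            sum_h
            + entropy(cols[f])
            + entropy(c)
            - joint_entropy([cols[s] for s in selected] + [cols[f], c])
        )
        ratio = num / den
    return (rel - red) * ratio


def reference_baseline_score(
    name: str,
    cols: List[np.ndarray],
    c: np.ndarray,
    selected: List[int],
    weights: Dict[int, float],
    f: int,
    beta: float,
    alpha: float,
) -> float:
    mi_c = mutual_information(cols[f], c)
    su_c = symmetrical_uncertainty(cols[f], c)
    if not selected:
        return su_c if name in ("dwfs", "iwfs", "raiw") else mi_c
    if name == "mifs":
        return mi_c - beta * sum(mutual_information(cols[f], cols[s]) for s in selected)
    if name == "mrmr":
        return mi_c - sum(
            mutual_information(cols[f], cols[s]) for s in selected
        ) / len(selected)
    if name == "nmifs":
        red = 0.0
        for s in selected:
            d = min(entropy(cols[f]), entropy(cols[s]))
            if d > 1e-12:
                red += mutual_information(cols[f], cols[s]) / d
        return mi_c - red / len(selected)
    if name == "cmi":
        h_f = entropy(cols[f])
        h_c = entropy(c)
        if h_f <= 1e-12 or h_c <= 1e-12:
            return mi_c
        red = 0.0
        for s in selected:
            h_s = entropy(cols[s])
            if h_s > 1e-12:
                red += (
                    mutual_information(cols[s], c)
                    * mutual_information(cols[f], cols[s])
                    / (h_s * h_c)
                )
        return mi_c - ((h_f - mi_c) / h_f) * red
    if name == "dwfs":
        return su_c * weights[f]
    if name == "iwfs":
        return weights[f] * (1.0 + su_c)
    if name == "raiw":
        last = selected[-1]
        return (
            su_c
            * (1.0 - alpha * symmetrical_uncertainty(cols[f], cols[last]))
            * weights[f]
        )
    if name == "cfr":
        total = 0.0
        for s in selected:
            cmi = joint_mutual_information(
                [cols[f], cols[s]], c
            ) - mutual_information(cols[s], c)
            total += cmi + interaction_gain(cols[f], cols[s], c)
        return total
    if name == "jmim":
        return min(
            joint_mutual_information([cols[f], cols[s]], c) for s in selected
        )
    if name == "dcsf":
        total = 0.0
        for s in selected:
            jmi = joint_mutual_information([cols[f], cols[s]], c)
            cmi_f = jmi - mutual_information(cols[s], c)
            cmi_s = jmi - mi_c
            total += cmi_f + cmi_s - mutual_information(cols[f], cols[s])
        return total
    if name == "mri":
        total = mi_c
        for s in selected:
            jmi = joint_mutual_information([cols[f], cols[s]], c)
            total += (jmi - mutual_information(cols[s], c)) + (jmi - mi_c)
        return total
    raise ValueError(name)


def reference_weight_factor(
    name: str, cols: List[np.ndarray], c: np.ndarray, f: int, s: int
) -> float:
    ig = interaction_gain(cols[f], cols[s], c)
    if name == "dwfs":
        denom, numer = entropy(cols[f]) + entropy(c), 2.0 * ig
    elif name == "iwfs":
        denom, numer = entropy(cols[f]) + entropy(cols[s]), ig
    else:
        denom, numer = entropy(cols[f]) + entropy(cols[s]) + entropy(c), 2.0 * ig
    return 1.0 if denom <= 1e-12 else 1.0 + numer / denom


def reference_greedy(
    X: np.ndarray,
    c: np.ndarray,
    M: int,
    name: str,
    beta: float = 0.5,
    alpha: float | None = None,
) -> List[int]:
    """From-scratch greedy selection; returns selected column indices in order."""
    p = X.shape[1]
    cols = [X[:, j] for j in range(p)]
    if alpha is None:
        alpha = 1.0 / p
    selected: List[int] = []
    weights = {j: 1.0 for j in range(p)}
    candidates = list(range(p))
    for _ in range(M):
        if not selected:
            if name in ("cria", "dwfs", "iwfs", "raiw"):
                scores = [symmetrical_uncertainty(cols[j], c) for j in candidates]
            else:
                scores = [mutual_information(cols[j], c) for j in candidates]
        elif name == "cria":
            scores = [reference_cria_score(cols, c, selected, j) for j in candidates]
        else:
            scores = [
                reference_baseline_score(
                    name, cols, c, selected, weights, j, beta, alpha
                )
                for j in candidates
            ]
        best = candidates[int(np.argmax(scores))]  # argmax keeps lowest index on ties
        selected.append(best)
        candidates.remove(best)
        if name in ("dwfs", "iwfs", "raiw"):
            for j in candidates:
                weights[j] *= reference_weight_factor(name, cols, c, j, best)
    return selected
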