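"""Candidate-feature scoring under CRIA and eleven comparator criteria.

Every criterion scores a candidate feature f against the current selection
state (the ordered selected subset Ω_S, the class label c, and — for the
dynamically weighted criteria — per-candidate weights).  The criteria fall
into three families:

* relevance−redundancy: MIFS, mRMR, NMIFS, and the conditional-mutual-
  information criterion (``cmi``), all built on pairwise mutual information;
* dynamically weighted: DWFS, IWFS and RAIW, which measure relevance with
  symmetrical uncertainty and multiply a per-candidate weight that grows with
  the three-way interaction information accumulated over selection rounds;
* three-way mutual information: CFR, JMIM, DCSF and MRI.

CRIA combines an SU-based relevance−redundancy difference with a
multivariate interaction factor: the ratio of the total correlation of
(Ω_S, f, c) to that of (Ω_S, c).  The ratio rewards candidates whose addition
increases the joint dependence of the selected set with the label beyond
what pairwise terms see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .infotheory import (
    _entropy_from_counts,
    entropy,
    joint_codes,
)
from .preprocess import DiscreteFeatureMatrix

__all__ = [
    "CRITERION_NAMES",
    "SU_SEEDED",
    "WEIGHTED",
    "CriterionSpec",
    "SelectionState",
    "interaction_factor_cria",
    "score_cria",
    "score_baseline",
    "update_weights",
]

CRITERION_NAMES = (
    "cria",
    "mifs",
    "mrmr",
    "nmifs",
    "cmi",
    "dwfs",
    "iwfs",
    "raiw",
    "cfr",
    "jmim",
    "dcsf",
    "mri",
)
#: criteria whose own relevance measure is SU, hence whose first pick is
#: argmax SU(f;c); all others seed with argmax I(f;c)
SU_SEEDED = frozenset({"cria", "dwfs", "iwfs", "raiw"})
#: criteria that maintain multiplicative per-candidate weights
WEIGHTED = frozenset({"dwfs", "iwfs", "raiw"})

_EPS = 1e-12


@dataclass(frozen=True)
class CriterionSpec:
    """A named criterion plus its tunable parameters.

    ``beta`` is the MIFS relevance/redundancy trade-off (≥ 0).  ``alpha`` is
    the RAIW redundancy coefficient; when None it defaults, at selection
    time, to 1/n_features of the matrix being ranked.
    """

    name: str
    beta: float = 0.5
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.name not in CRITERION_NAMES:
            raise ValueError(
                f"unknown criterion {self.name!r}; expected one of {CRITERION_NAMES}"
            )
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def _code_entropy(codes: np.ndarray) -> float:
    return _entropy_from_counts(np.bincount(codes))


class SelectionState:
    """Greedy-selection bookkeeping over one discrete feature matrix.

    Holds Ω_S (ordered), the candidate set, per-candidate weights
    (initialized to 1), and memoized information quantities.  The joint
    row-code of (Ω_S, c) is extended incrementally as features are selected,
    so each total-correlation evaluation costs one column merge; the cached
    route is contract-tested against from-scratch recomputation.
    """

    def __init__(self, matrix: DiscreteFeatureMatrix):
        self.matrix = matrix
        self.selected: List[int] = []
        self.candidates: Set[int] = set(range(matrix.n_features))
        self.weights: Dict[int, float] = {j: 1.0 for j in self.candidates}

        self._cols = [matrix.values[:, j] for j in range(matrix.n_features)]
        self._c = matrix.label_codes
        self.h_c = entropy(self._c)
        self.h = [entropy(col) for col in self._cols]

        self._mi_c: Dict[int, float] = {}
        self._mi_pair: Dict[Tuple[int, int], float] = {}
        self._jmi_pair_c: Dict[Tuple[int, int], float] = {}
        # joint row-code of (Ω_S, c); starts as the label codes themselves
        self._code_sc: np.ndarray = joint_codes([self._c])
        self._sum_h_selected = 0.0

    # -- identifiers -------------------------------------------------------
    def feature_index(self, feature_id: str) -> int:
        return self.matrix.feature_ids.index(feature_id)

    def feature_id(self, index: int) -> str:
        return self.matrix.feature_ids[index]

    # -- memoized pairwise quantities -------------------------------------
    def mi_c(self, i: int) -> float:
        if i not in self._mi_c:
            h_joint = _code_entropy(joint_codes([self._cols[i], self._c]))
            self._mi_c[i] = max(self.h[i] + self.h_c - h_joint, 0.0)
        return self._mi_c[i]

    def su_c(self, i: int) -> float:
        denom = self.h[i] + self.h_c
        return 0.0 if denom <= _EPS else min(2.0 * self.mi_c(i) / denom, 1.0)

    def mi_pair(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._mi_pair:
            h_joint = _code_entropy(joint_codes([self._cols[i], self._cols[j]]))
            self._mi_pair[key] = max(self.h[i] + self.h[j] - h_joint, 0.0)
        return self._mi_pair[key]

    def su_pair(self, i: int, j: int) -> float:
        denom = self.h[i] + self.h[j]
        return 0.0 if denom <= _EPS else min(2.0 * self.mi_pair(i, j) / denom, 1.0)

    def jmi_pair_c(self, i: int, j: int) -> float:
        """I(f_i, f_j; c)."""
        key = (i, j) if i < j else (j, i)
        if key not in self._jmi_pair_c:
            pair = joint_codes([self._cols[i], self._cols[j]])
            h_pair = _code_entropy(pair)
            h_pair_c = _code_entropy(joint_codes([pair, self._c]))
            self._jmi_pair_c[key] = max(h_pair + self.h_c - h_pair_c, 0.0)
        return self._jmi_pair_c[key]

    def cmi_c_given(self, i: int, j: int) -> float:
        """I(f_i; c | f_j) = I(f_i, f_j; c) − I(f_j; c)."""
        return max(self.jmi_pair_c(i, j) - self.mi_c(j), 0.0)

    def interaction_gain(self, i: int, j: int) -> float:
        """I(f_i; f_j; c) = I(f_i, f_j; c) − I(f_i; c) − I(f_j; c)."""
        return self.jmi_pair_c(i, j) - self.mi_c(i) - self.mi_c(j)

    # -- total correlation of the selected set ----------------------------
    def tc_selected_with_label(self) -> float:
        """TC(Ω_S, c) = Σ_{s∈Ω_S} H(f_s) + H(c) − H(Ω_S, c)."""
        if not self.selected:
            raise ValueError("Ω_S is empty; stage 1 must select a feature first")
        return max(
            self._sum_h_selected + self.h_c - _code_entropy(self._code_sc), 0.0
        )

    def tc_selected_plus_with_label(self, i: int) -> float:
        """TC(Ω_S ∪ {f_i}, c) via one merge with the cached (Ω_S, c) code."""
        if not self.selected:
            raise ValueError("Ω_S is empty; stage 1 must select a feature first")
        merged = joint_codes([self._code_sc, self._cols[i]])
        return max(
            self._sum_h_selected + self.h[i] + self.h_c - _code_entropy(merged),
            0.0,
        )

    # -- state transition --------------------------------------------------
    def select(self, i: int) -> None:
        if i not in self.candidates:
            raise ValueError(f"feature index {i} is not a candidate")
        self.candidates.remove(i)
        self.weights.pop(i, None)
        self.selected.append(i)
        self._sum_h_selected += self.h[i]
        self._code_sc = joint_codes([self._code_sc, self._cols[i]])


def interaction_factor_cria(state: SelectionState, i: int) -> float:
    """Total-correlation ratio TC(Ω_S, f_i, c) / TC(Ω_S, c).

    Measures how much multivariate dependence the candidate adds to the
    selected set's joint relationship with the label.  When the denominator
    vanishes (a selected set carrying no dependence with the label) the
    factor is neutral: 1.
    """
    denom = state.tc_selected_with_label()
    if denom <= _EPS:
        return 1.0
    return state.tc_selected_plus_with_label(i) / denom


def score_cria(state: SelectionState, i: int) -> float:
    """J(f) = [SU(f,c) − mean_{fs∈Ω_S} SU(f,fs)] × interaction factor."""
    if not state.selected:
        raise ValueError("Ω_S is empty; stage 1 must select a feature first")
    redundancy = sum(state.su_pair(i, s) for s in state.selected) / len(state.selected)
    return (state.su_c(i) - redundancy) * interaction_factor_cria(state, i)


def _score_mifs(spec, state, i):
    return state.mi_c(i) - spec.beta * sum(state.mi_pair(i, s) for s in state.selected)


def _score_mrmr(spec, state, i):
    ns = len(state.selected)
    if ns == 0:
        return state.mi_c(i)
    return state.mi_c(i) - sum(state.mi_pair(i, s) for s in state.selected) / ns


def _score_nmifs(spec, state, i):
    ns = len(state.selected)
    if ns == 0:
        return state.mi_c(i)
    red = 0.0
    for s in state.selected:
        denom = min(state.h[i], state.h[s])
        if denom > _EPS:
            red += state.mi_pair(i, s) / denom
    return state.mi_c(i) - red / ns


def _score_cmi(spec, state, i):
    # J = I(f;c) − [H(f|c)/H(f)] Σ I(fs;c) I(f;fs) / (H(fs) H(c))
    rel = state.mi_c(i)
    if state.h[i] <= _EPS or state.h_c <= _EPS:
        return rel
    h_f_given_c = state.h[i] - rel
    red = 0.0
    for s in state.selected:
        if state.h[s] > _EPS:
            red += state.mi_c(s) * state.mi_pair(i, s) / (state.h[s] * state.h_c)
    return rel - (h_f_given_c / state.h[i]) * red


def _score_dwfs(spec, state, i):
    return state.su_c(i) * state.weights[i]


def _score_iwfs(spec, state, i):
    return state.weights[i] * (1.0 + state.su_c(i))


def _score_raiw(spec, state, i):
    alpha = spec.alpha if spec.alpha is not None else 1.0 / state.matrix.n_features
    if not state.selected:
        return state.su_c(i) * state.weights[i]
    last = state.selected[-1]  # f_s: the most recently selected feature
    return state.su_c(i) * (1.0 - alpha * state.su_pair(i, last)) * state.weights[i]


def _score_cfr(spec, state, i):
    if not state.selected:
        return state.mi_c(i)
    return sum(
        state.cmi_c_given(i, s) + state.interaction_gain(i, s) for s in state.selected
    )


def _score_jmim(spec, state, i):
    if not state.selected:
        return state.mi_c(i)
    return min(state.jmi_pair_c(i, s) for s in state.selected)


def _score_dcsf(spec, state, i):
    if not state.selected:
        return state.mi_c(i)
    return sum(
        state.cmi_c_given(i, s) + state.cmi_c_given(s, i) - state.mi_pair(i, s)
        for s in state.selected
    )


def _score_mri(spec, state, i):
    return state.mi_c(i) + sum(
        state.cmi_c_given(i, s) + state.cmi_c_given(s, i) for s in state.selected
    )


_BASELINES = {
    "mifs": _score_mifs,
    "mrmr": _score_mrmr,
    "nmifs": _score_nmifs,
    "cmi": _score_cmi,
    "dwfs": _score_dwfs,
    "iwfs": _score_iwfs,
    "raiw": _score_raiw,
    "cfr": _score_cfr,
    "jmim": _score_jmim,
    "dcsf": _score_dcsf,
    "mri": _score_mri,
}


def score_baseline(spec: CriterionSpec, state: SelectionState, i: int) -> float:
    """Evaluate a comparator criterion's J for candidate ``i``.

    With an empty Ω_S (the engine's first pick) every criterion reduces to
    its own relevance measure: SU(f;c) for the weighted SU-based criteria,
    I(f;c) for the rest.
    """
    if spec.name == "cria":
        return score_cria(state, i)
    try:
        fn = _BASELINES[spec.name]
    except KeyError:
        raise ValueError(f"unknown criterion {spec.name!r}") from None
    return fn(spec, state, i)


def _weight_factor(name: str, state: SelectionState, i: int, s: int) -> float:
    ig = state.interaction_gain(i, s)
    if name == "dwfs":
        denom = state.h[i] + state.h_c
    elif name == "iwfs":
        denom = state.h[i] + state.h[s]
    else:  # raiw
        denom = state.h[i] + state.h[s] + state.h_c
    if denom <= _EPS:
        return 1.0
    numer = 2.0 * ig if name in ("dwfs", "raiw") else ig
    return 1.0 + numer / denom


def update_weights(
    spec: CriterionSpec, state: SelectionState, just_selected: int
) -> None:
    """Multiply every remaining candidate's weight by its interaction factor
    with the feature just selected (DWFS/IWFS/RAIW only; no-op otherwise)."""
    if spec.name not in WEIGHTED:
        warnings.warn(
            f"criterion {spec.name!r} does not maintain weights; update ignored",
            stacklevel=2,
        )
        return
    if just_selected not in state.selected:
        raise ValueError("just_selected must already be in Ω_S")
    for i in state.candidates:
        state.weights[i] *= _weight_factor(spec.name, state, i, just_selected)
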