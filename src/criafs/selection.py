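"""Greedy forward-selection engines and the incremental-feature-selection curve.

Selection runs in two stages.  Stage 1 picks the "main effect feature": the
single feature with the largest relevance to the class label under the
criterion's own relevance measure (symmetrical uncertainty for the SU-seeded
criteria, mutual information otherwise).  Stage 2 repeatedly scores every
remaining candidate against the current selected subset and adds the argmax,
until exactly M features are selected.  Ties resolve to the lowest original
column index, making every trace deterministic.

The IFS (incremental feature selection) curve then evaluates growing
prefixes of the ranked list with a classifier under repeated stratified
cross-validation and reports the smallest prefix size attaining the maximum
mean accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np

from .criteria import (
    SU_SEEDED,
    WEIGHTED,
    CriterionSpec,
    SelectionState,
    interaction_factor_cria,
    score_cria,
    score_baseline,
    update_weights,
)
from .preprocess import DiscreteFeatureMatrix

__all__ = [
    "TraceRecord",
    "SelectionTrace",
    "IFSCurve",
    "select_main_effect",
    "cria_select",
    "greedy_select",
    "ifs_curve",
]


@dataclass(frozen=True)
class TraceRecord:
    round: int
    feature_id: str
    score: float
    relevance: float
    redundancy: float  # NaN for criteria without an explicit redundancy term
    interaction_factor: float  # NaN for non-CRIA criteria


@dataclass
class SelectionTrace:
    records: List[TraceRecord]
    criterion: CriterionSpec

    @property
    def feature_ids(self) -> List[str]:
        return [r.feature_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class IFSCurve:
    """Mean cross-validated accuracy for each ranked-prefix size 1..K."""

    sizes: List[int]
    accuracies: List[float]

    @property
    def optimal_k(self) -> int:
        """Smallest prefix size attaining the maximum mean accuracy."""
        best = max(self.accuracies)
        for k, a in zip(self.sizes, self.accuracies):
            if a == best:
                return k
        raise RuntimeError("empty curve")

    @property
    def accuracy_at_optimal(self) -> float:
        return self.accuracies[self.sizes.index(self.optimal_k)]


def _argmax_lowest_index(scores: Sequence[float], indices: Sequence[int]) -> int:
    """Argmax over (score, index) with ties going to the lowest column index."""
    best_i, best_s = None, -math.inf
    for s, i in sorted(zip(scores, indices), key=lambda t: t[1]):
        if s > best_s + 0.0:  # strict: first (lowest-index) max wins
            best_s, best_i = s, i
    return best_i


def select_main_effect(m: DiscreteFeatureMatrix) -> str:
    """The feature with the largest SU with the class label (stage 1)."""
    if m.n_features < 1:
        raise ValueError("matrix has no features")
    if np.unique(m.label_codes).size < 2:
        raise ValueError("labels are constant; selection is undefined")
    state = SelectionState(m)
    idx = _argmax_lowest_index(
        [state.su_c(j) for j in range(m.n_features)], range(m.n_features)
    )
    return m.feature_ids[idx]


def _check_m(m: DiscreteFeatureMatrix, M: int) -> None:
    if M < 1:
        raise ValueError("M must be at least 1")
    if M > m.n_features:
        raise ValueError(f"M={M} exceeds the number of features ({m.n_features})")


def greedy_select(
    m: DiscreteFeatureMatrix, M: int, spec: CriterionSpec
) -> SelectionTrace:
    """Rank M features by greedy forward selection under any criterion.

    The first record stores the stage-1 relevance value in its score field;
    subsequent records store the criterion's J at the round the feature won.
    """
    _check_m(m, M)
    if np.unique(m.label_codes).size < 2:
        raise ValueError("labels are constant; selection is undefined")
    state = SelectionState(m)
    records: List[TraceRecord] = []

    # stage 1: the main effect feature under the criterion's relevance measure
    if spec.name in SU_SEEDED:
        rel = [state.su_c(j) for j in range(m.n_features)]
    else:
        rel = [state.mi_c(j) for j in range(m.n_features)]
    first = _argmax_lowest_index(rel, range(m.n_features))
    state.select(first)
    records.append(
        TraceRecord(1, m.feature_ids[first], rel[first], rel[first], math.nan, math.nan)
    )
    if spec.name in WEIGHTED:
        update_weights(spec, state, first)

    # stage 2: greedy rounds
    for rnd in range(2, M + 1):
        cand = sorted(state.candidates)
        if spec.name == "cria":
            scores = [score_cria(state, i) for i in cand]
        else:
            scores = [score_baseline(spec, state, i) for i in cand]
        pick = _argmax_lowest_index(scores, cand)
        score = scores[cand.index(pick)]
        if spec.name == "cria":
            redundancy = sum(
                state.su_pair(pick, s) for s in state.selected
            ) / len(state.selected)
            record = TraceRecord(
                rnd,
                m.feature_ids[pick],
                score,
                state.su_c(pick),
                redundancy,
                interaction_factor_cria(state, pick),
            )
        else:
            relevance = (
                state.su_c(pick) if spec.name in SU_SEEDED else state.mi_c(pick)
            )
            record = TraceRecord(
                rnd, m.feature_ids[pick], score, relevance, math.nan, math.nan
            )
        state.select(pick)
        records.append(record)
        if spec.name in WEIGHTED:
            update_weights(spec, state, pick)

    return SelectionTrace(records, spec)


def cria_select(m: DiscreteFeatureMatrix, M: int) -> SelectionTrace:
    """Two-stage CRIA selection: SU main-effect seed, then greedy rounds
    maximizing the relevance−redundancy × interaction-factor criterion."""
    return greedy_select(m, M, CriterionSpec("cria"))


def ifs_curve(
    m: DiscreteFeatureMatrix,
    trace: SelectionTrace,
    classifier_factory: Callable[[], object],
    k_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> IFSCurve:
    """Cross-validated accuracy of each ranked prefix of the trace.

    ``classifier_factory`` returns a fresh estimator with the scikit-learn
    fit/predict contract each time it is called.  For each prefix size
    k = 1..|trace| the mean test accuracy over n_repeats × k_folds splits is
    recorded; one classifier is trained per (prefix, fold, repeat).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if m.n_samples < k_folds:
        raise ValueError("fewer samples than folds")
    cols = [m.feature_ids.index(fid) for fid in trace.feature_ids]
    X = m.values[:, cols]
    y = m.label_codes
    K = len(cols)
    correct = np.zeros(K, dtype=float)
    total = 0
    for rep in range(n_repeats):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=k_folds, shuffle=True, random_state=seed + rep)
        for train, test in splitter.split(X, y):
            total += test.size
            for k in range(1, K + 1):
                clf = classifier_factory()
                clf.fit(X[train, :k], y[train])
                pred = np.asarray(clf.predict(X[test, :k]))
                correct[k - 1] += int(np.sum(pred == y[test]))
    accuracies = (correct / total).tolist()
    return IFSCurve(sizes=list(range(1, K + 1)), accuracies=accuracies)
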