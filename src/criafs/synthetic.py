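"""Seeded generator of discrete fixtures with known dependence structure.

The generator emulates, at small scale, exactly the structure the selection
criteria are designed to tell apart:

* **main** features — the class label passed through a symmetric category-flip
  channel, so each is marginally informative;
* **redundant** features — noisy copies of designated main features, carrying
  little information beyond their source;
* **interaction pairs** — for binary labels, a uniform random bit u paired
  with u XOR label: each member is marginally independent of the label while
  the pair jointly determines it (before noise);
* **noise** features — independent of everything.

All randomness flows from one seeded generator, so a (spec, seed) pair yields
byte-identical datasets.  The default configuration — 1000 samples, 5 main
features, 5 redundant copies, 40 noise features, a 5% flip channel — is the
standing study condition used throughout the test-suite and examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .infotheory import mutual_information, symmetrical_uncertainty
from .preprocess import DiscreteFeatureMatrix

__all__ = ["SyntheticSpec", "make_dataset", "expected_structure_report"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 1000
    n_classes: int = 2
    n_main: int = 5
    n_redundant: int = 5
    n_interaction_pairs: int = 0
    n_noise: int = 40
    label_flip_rate: float = 0.0
    feature_noise_rate: float = 0.05
    noise_alphabet: int = 2
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_main,
            self.n_redundant,
            self.n_interaction_pairs,
            self.n_noise,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be non-negative")
        if self.n_features < 1:
            raise ValueError("at least one feature is required")
        if not (0 <= self.label_flip_rate < 1):
            raise ValueError("label_flip_rate must be in [0, 1)")
        if not (0 <= self.feature_noise_rate < 1):
            raise ValueError("feature_noise_rate must be in [0, 1)")
        if self.n_interaction_pairs > 0 and self.n_classes != 2:
            raise ValueError("interaction pairs require binary labels")
        if self.n_redundant > 0 and self.n_main == 0:
            raise ValueError("redundant features need a main feature to copy")
        if self.n_classes < 2:
            raise ValueError("at least two classes are required")

    @property
    def n_features(self) -> int:
        return (
            self.n_main
            + self.n_redundant
            + 2 * self.n_interaction_pairs
            + self.n_noise
        )


def _flip_channel(
    x: np.ndarray, rate: float, n_categories: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric noise: with probability ``rate`` replace a code by a uniform
    draw among the *other* categories."""
    if rate == 0.0 or n_categories < 2:
        return x.copy()
    out = x.copy()
    hit = rng.random(x.size) < rate
    shift = rng.integers(1, n_categories, size=x.size)
    out[hit] = (x[hit] + shift[hit]) % n_categories
    return out


def make_dataset(
    spec: SyntheticSpec,
) -> tuple[DiscreteFeatureMatrix, Dict[str, Dict[str, Optional[str]]]]:
    """Generate the fixture and a role map recording each column's provenance.

    The role map maps feature id → {"role": main|redundant|interaction|noise,
    "source": the main feature copied (redundant) or the pair partner
    (interaction), else None}.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = rng.integers(0, spec.n_classes, size=n)

    columns = []
    ids = []
    role_map: Dict[str, Dict[str, Optional[str]]] = {}

    main_cols = []
    for i in range(spec.n_main):
        col = _flip_channel(labels, spec.feature_noise_rate, spec.n_classes, rng)
        main_cols.append(col)
        fid = f"main_{i}"
        ids.append(fid)
        columns.append(col)
        role_map[fid] = {"role": "main", "source": None}

    for i in range(spec.n_redundant):
        src = i % spec.n_main
        col = _flip_channel(
            main_cols[src], spec.feature_noise_rate, spec.n_classes, rng
        )
        fid = f"redundant_{i}"
        ids.append(fid)
        columns.append(col)
        role_map[fid] = {"role": "redundant", "source": f"main_{src}"}

    for i in range(spec.n_interaction_pairs):
        u = rng.integers(0, 2, size=n)
        a = _flip_channel(u, spec.feature_noise_rate, 2, rng)
        b = _flip_channel(u ^ labels, spec.feature_noise_rate, 2, rng)
        fa, fb = f"interaction_{i}a", f"interaction_{i}b"
        ids.extend([fa, fb])
        columns.extend([a, b])
        role_map[fa] = {"role": "interaction", "source": fb}
        role_map[fb] = {"role": "interaction", "source": fa}

    for i in range(spec.n_noise):
        col = rng.integers(0, spec.noise_alphabet, size=n)
        fid = f"noise_{i}"
        ids.append(fid)
        columns.append(col)
        role_map[fid] = {"role": "noise", "source": None}

    observed_labels = _flip_channel(labels, spec.label_flip_rate, spec.n_classes, rng)
    matrix = DiscreteFeatureMatrix(np.column_stack(columns), ids, observed_labels)
    return matrix, role_map


def expected_structure_report(
    matrix: DiscreteFeatureMatrix, role_map: Dict[str, Dict[str, Optional[str]]]
) -> pd.DataFrame:
    """Empirical SU/MI of every feature with the label and with its source.

    One row per feature: role, source, su_label, mi_label, su_source (NaN for
    features without a source).  Intended for assertions about the generated
    structure rather than for end-user analysis.
    """
    if set(role_map) != set(matrix.feature_ids):
        raise ValueError("role map does not match the matrix's feature ids")
    rows = []
    for fid in matrix.feature_ids:
        info = role_map[fid]
        col = matrix.column(fid)
        su_source = np.nan
        if info["source"] is not None:
            su_source = symmetrical_uncertainty(col, matrix.column(info["source"]))
        rows.append(
            {
                "feature_id": fid,
                "role": info["role"],
                "source": info["source"],
                "su_label": symmetrical_uncertainty(col, matrix.label_codes),
                "mi_label": mutual_information(col, matrix.label_codes),
                "su_source": su_source,
            }
        )
    return pd.DataFrame(rows)
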