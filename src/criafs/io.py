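"""Reading and writing matrices, traces, curves and run configurations.

Matrices travel as delimited text with a header row: samples-as-rows with a
label column (default ``class``) is canonical; GISTIC-style genes-as-rows
matrices (one row per gene, one column per sample) are transposed on read
and need a separate label file (one label per line, sample order).  The
delimiter is inferred from the extension: ``.tsv`` tab, ``.csv`` comma.

Floating-point values in TSV artifacts are written with 6 significant
digits for readable diffs; JSON artifacts keep full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .criteria import CriterionSpec
from .preprocess import DiscreteFeatureMatrix, FeatureMatrix
from .selection import IFSCurve, SelectionTrace, TraceRecord

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_trace",
    "read_trace",
    "write_curve",
    "write_json",
]

_FMT = "%.6g"


@dataclass
class RunConfig:
    """Fully resolved parameters of one CLI run, echoed into the output dir."""

    command: str
    input: Optional[str] = None
    orientation: str = "samples-as-rows"
    label_column: str = "class"
    label_file: Optional[str] = None
    criterion: str = "cria"
    beta: float = 0.5
    alpha: Optional[float] = None
    m: int = 200
    classifier: str = "knn1"
    k_folds: int = 10
    n_repeats: int = 10
    seed: int = 0
    stratified: bool = True
    out: Optional[str] = None

    def dump(self, directory: Path) -> Path:
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "run_config.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_labels(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"label file {path} is empty")
    return np.asarray(lines)


def read_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    label_column: str = "class",
    label_file: Optional[str | Path] = None,
) -> FeatureMatrix:
    """Load a matrix into canonical samples-as-rows orientation.

    Genes-as-rows inputs (first column gene ids, remaining columns samples)
    are transposed; their labels must come from ``label_file``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_delimiter(path))
    if len(set(header)) != len(header):  # pandas silently renames dupes
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate feature ids: {dupes}")
    df = pd.read_csv(path, sep=_delimiter(path))
    if orientation == "genes-as-rows":
        gene_ids = df.iloc[:, 0].astype(str)
        if gene_ids.duplicated().any():
            dupes = sorted(gene_ids[gene_ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate feature ids: {dupes}")
        body = df.iloc[:, 1:].set_axis(gene_ids, axis=0).T
        if label_file is None:
            raise ValueError("genes-as-rows input requires a label file")
        labels = read_labels(label_file)
        if labels.size != body.shape[0]:
            raise ValueError(
                f"label file has {labels.size} entries but matrix has "
                f"{body.shape[0]} samples"
            )
        values = _numeric_values(body, path)
        return FeatureMatrix(values, list(body.columns), labels)
    if orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if label_file is not None:
        labels = read_labels(label_file)
        feature_df = df
    else:
        if label_column not in df.columns:
            raise ValueError(
                f"label column {label_column!r} not found in {path.name}; "
                f"columns are {list(df.columns)}"
            )
        labels = df[label_column].to_numpy()
        feature_df = df.drop(columns=[label_column])
    ids = [str(c) for c in feature_df.columns]
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ValueError(f"duplicate feature ids: {dupes}")
    values = _numeric_values(feature_df, path)
    return FeatureMatrix(values, ids, labels)


def _numeric_values(df: pd.DataFrame, path: Path) -> np.ndarray:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at data row {r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path.name} at data row {r}, column {df.columns[c]!r}"
        )
    return numeric.to_numpy(dtype=float)


def write_matrix(
    m: FeatureMatrix | DiscreteFeatureMatrix,
    path: str | Path,
    label_column: str = "class",
) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, columns=m.feature_ids)
    df.insert(0, label_column, m.labels)
    df.to_csv(path, sep=_delimiter(path), index=False, float_format=_FMT)


def write_trace(trace: SelectionTrace, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "rank": r.round,
            "feature_id": r.feature_id,
            "score": r.score,
            "relevance": r.relevance,
            "redundancy": r.redundancy,
            "interaction_factor": r.interaction_factor,
        }
        for r in trace.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_trace(path: str | Path, criterion: Optional[CriterionSpec] = None) -> SelectionTrace:
    df = pd.read_csv(Path(path), sep="\t")
    records = [
        TraceRecord(
            int(row["rank"]),
            str(row["feature_id"]),
            float(row["score"]),
            float(row["relevance"]),
            float(row["redundancy"]) if not pd.isna(row["redundancy"]) else math.nan,
            float(row["interaction_factor"])
            if not pd.isna(row["interaction_factor"])
            else math.nan,
        )
        for _, row in df.iterrows()
    ]
    return SelectionTrace(records, criterion or CriterionSpec("cria"))


def write_curve(curve: IFSCurve, tsv_path: str | Path, json_path: str | Path) -> None:
    pd.DataFrame({"k": curve.sizes, "mean_accuracy": curve.accuracies}).to_csv(
        Path(tsv_path), sep="\t", index=False, float_format=_FMT
    )
    write_json(
        {"optimal_k": curve.optimal_k, "accuracy_at_optimal": curve.accuracy_at_optimal},
        json_path,
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
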