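"""Repeated cross-validation and one-vs-rest classification metrics.

Run: python examples/06_evaluation_metrics.py
"""

from criafs.evaluation import cross_validate, make_classifier, run_std
from criafs.selection import cria_select
from criafs.synthetic import SyntheticSpec, make_dataset

spec = SyntheticSpec(n_samples=400, n_classes=3, n_main=4, n_redundant=2,
                     n_noise=10, feature_noise_rate=0.15, seed=4)
matrix, _ = make_dataset(spec)

subset = cria_select(matrix, 4).feature_ids
print(f"evaluating subset {subset} with 1-NN, 10-fold CV × 5 repeats\n")

report = cross_validate(
    matrix, subset, make_classifier("knn1"), k_folds=10, n_repeats=5, seed=0
)
print(f"mean accuracy over repeats: {report.mean_accuracy:.4f} "
      f"± {report.std:.4f} (population std over per-repeat accuracies)")
print("\nper-class one-vs-rest metrics (pooled over folds):")
for cls, mets in report.per_class.items():
    print(f"  class {cls}: precision {mets['precision']:.4f}  "
          f"recall {mets['recall']:.4f}  F1 {mets['f1']:.4f}")
print(f"macro F1: {report.macro_f1:.4f}")
print(f"\npooled confusion matrix (rows = true class):")
print(report.confusion.counts)

print(f"\nrun_std on a two-point example [0, 1]: {run_std([0.0, 1.0])}")
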