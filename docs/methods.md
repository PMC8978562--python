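# Methods

This note records the statistical model behind `criafs`, the parameter
defaults and why they were chosen, the numerical conventions, and the
package's known limitations.  It makes no empirical claims beyond what the
test suite and `scripts/acceptance.py` compute.

## Model and procedure

Input is a discrete feature matrix: `n` samples × `p` features, each cell
a small-integer code, plus a categorical class label per sample.  The
intended domain is gene-level copy-number call matrices (GISTIC-style
−2…2 codes), but nothing is CNV-specific: any discrete matrix works, and
continuous matrices can be discretized first.

All information quantities are plug-in estimates: empirical cell
frequencies substituted into the discrete formulas, logarithms base 2
(units are bits), with the convention `0·log 0 = 0`.  Joint entropies are
computed by exact row-tuple counting — each sample's value combination is
collapsed to a single joint code — so no independence or smoothness
assumption enters anywhere.

Selection is greedy forward search.  Round one picks the feature with
maximal symmetrical uncertainty `SU(f, c)` with the label (for the
SU-seeded criteria — CRIA, DWFS, IWFS, RAIW) or maximal mutual information
`I(f; c)` (all others).  Each later round scores every remaining candidate
against the selected set `S` and picks the argmax; the CRIA score is

    J(f) = [ SU(f, c) − (1/|S|) Σ_{s∈S} SU(f, s) ] × TC(S∪{f,c}) / TC(S∪{c})

where `TC` is total correlation.  The eleven comparator criteria use
their standard forms (MIFS's β-weighted redundancy sum, mRMR's mean
redundancy, NMIFS's normalized redundancy, conditional-MI and
joint-MI variants, and the weight-updating family DWFS/IWFS/RAIW).

After ranking, incremental feature selection (IFS) evaluates each ranked
prefix of size 1…M by repeated stratified k-fold cross-validation with a
bundled classifier; the reported optimal subset size is the **smallest**
prefix attaining the maximum mean accuracy.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| `M` (features to rank) | 200 | large enough that an IFS sweep over prefixes covers the useful range on gene-level matrices, while keeping the O(M·p) scoring loop tractable; capped at `p` |
| `beta` (MIFS redundancy weight) | 0.5 | midpoint of the 0.4–1.0 range commonly recommended for MIFS; the criterion's originator left it data-dependent, so it is exposed as a flag |
| `alpha` (RAIW redundancy attenuation) | `1/p` | scales the penalty to the feature count so the attenuation term stays comparable across matrix widths; exposed as a flag |
| `k_folds` | 10 | conventional bias/variance compromise for n in the hundreds-to-thousands range |
| `n_repeats` | 10 | repeated CV with distinct seeded shuffles; the per-repeat accuracies feed the reported mean ± std |
| classifier | `knn1` | 1-nearest-neighbour is hyperparameter-free and sensitive to irrelevant features, which makes IFS curves informative; `naive_bayes`, `tree`, `majority` are bundled alternatives |
| `stratified` | true | preserves class proportions per fold; disable (`--no-stratify`) only with near-balanced classes and larger n |
| seed | 0 | every stochastic step (generator, fold shuffles) derives from one integer seed; identical seeds give byte-identical artifacts |

Synthetic generator defaults: 1000 samples, 2 classes, 5 main-effect
features, 5 redundant copies, 0 interaction pairs, 40 noise features,
feature noise rate 0.05, label flip rate 0.  These are the package's
standard fixture conditions — a class-informative minority of features
inside a noise-dominated matrix — and every number reported by the test
suite and acceptance script on synthetic data refers to them unless stated
otherwise.

## What the generator emulates, and what it does not

Emulated: a small set of class-predictive discrete markers
(`main_*`: the label passed through a symmetric flip channel), strong
marker–marker redundancy (`redundant_*`: noisy copies of main features),
purely synergistic pairs (`interaction_*`: two binary columns whose XOR
tracks the label while each member alone is independent of it — binary
classes only), bulk irrelevant features (`noise_*`: uniform over a
configurable alphabet), and label noise (a flip channel on the returned
labels).  A role map records each column's ground-truth role and source,
enabling exact recovery assertions.

Not emulated: the spatial correlation structure of real CNV data
(arm-level events making physically adjacent genes redundant), non-uniform
marker alphabets, class imbalance, missing calls, batch effects, and any
dependence between noise features.  Conclusions about ranking behaviour on
the fixture therefore transfer to real matrices only qualitatively.

## Numerical conventions

- Entropies from counts can come out a hair negative through floating
  point; values in `(−1e−12, 0)` are clamped to 0, anything more negative
  raises.
- CRIA's interaction-factor denominator `TC(S∪{c})` is guarded: when it is
  ≤ 1e−12 the factor is set to 1 (no interaction evidence either way).
  Note the factor can be large when the denominator is merely small — a
  selected set nearly independent of the label makes the ratio
  ill-conditioned (see limitations).
- Score ties in greedy selection break to the lowest column index, making
  rankings deterministic and order-independent of dictionary iteration.
- Selection stops at exactly `M` features; traces preserve selection
  order, and the round-1 record stores the seed relevance value in its
  score field (redundancy and interaction columns are NaN where
  undefined).
- One-vs-rest precision/recall/F1 define `0/0 = 0` (a class never
  predicted gets precision 0, not NaN).
- The spread over repeated CV runs is the population standard deviation of
  per-repeat accuracies (divisor `n_runs`), with an exact-zero shortcut
  when all repeats agree.
- Per-class metrics default to pooling the confusion counts over all folds
  and repeats before computing ratios (`per_class_mode="pooled"`);
  `"averaged"` computes per-repeat metrics and averages them.  Pooled is
  the default because small folds can lack a class entirely, which makes
  per-fold ratios noisy or undefined.
- MDLP discretization is fit once on the full matrix against the labels,
  not per CV training fold.  When discretization is part of a pipeline
  whose accuracy is being estimated, fitting it outside the CV loop leaks
  label information into the test folds; the package keeps the global fit
  because ranking and discretization are treated as a preprocessing stage
  whose output is the object under study, but accuracy estimates should
  be read accordingly.
- Scoring caches the joint code of `(S, c)` incrementally, so each round
  costs one joint-count pass per candidate rather than recomputing the
  full selected-set entropy stack; a contract test pins cached and
  uncached scoring to identical results.

## Limitations

- Plug-in estimators are biased upward for entropy-derived quantities at
  small `n` relative to the joint alphabet; CRIA's total-correlation terms
  involve the full selected set, so the bias grows with `|S|`.  Rankings
  deep into a trace (large `M`, small `n`) should be treated with caution.
- The interaction factor's denominator shrinks when the selected set
  carries little label information, inflating the factor; the guard only
  catches the exactly-degenerate case.
- Greedy forward selection is not globally optimal for any of the twelve
  criteria; it commits to earlier picks.
- Scoring one candidate is `O(n)` per round but with a constant that grows
  with the joint-code collapse; a full ranking is `O(M·p·n)`.  The default
  fixture (1000 × 50, M = 20) ranks in seconds; matrices with tens of
  thousands of genes will want a smaller `M` or pre-filtering.
- The IFS accuracy curve uses the same data for ranking and evaluation;
  it estimates subset quality for this matrix, not generalization of the
  whole select-then-classify pipeline.  An outer CV around selection would
  be required for that.
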