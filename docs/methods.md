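# Methods

## Model

The GkNN estimator predicts a query chemical's activity as a power mean of
its `k` nearest training activities weighted by powered Tanimoto
similarities:

    Â_i = ( Σ_j A_j^x S_ij^y / Σ_j S_ij^y )^(1/x),   x ≥ 0, y ≥ 0.

Activities and similarities both live on `[0, 1]`. The estimate is a
weighted power mean, so it always lies between the smallest and largest
neighbor activity used. The model assumes the similarity principle —
structurally similar chemicals have similar activities — and its accuracy
degrades exactly where that assumption fails (activity cliffs, quantified
below). Reference variants: arithmetic kNN (the `x = 1, y = 0` special
case), geometric kNN (`Π A_j^{1/k}`), and exponential kNN
(`Σ A_j e^{−x d_ij} / Σ e^{−x d_ij}` with `d_ij = 1/S_ij − 1`).

Prediction confidence is `q_i = max_j S_ij` over the training set, the
standard similarity-to-nearest-neighbor applicability-domain proxy;
`stratify_by_confidence` recomputes metrics above confidence cutoffs.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | neighbors used | 10 | grid `{1,2,3,5,7,10,15,20,30,50}` |
| `x` | activity-space exponent | 1.0 | grid `{0.0 … 50.0}` (17 values) |
| `y` | structure-space exponent | 1.0 | gknn only; same grid |
| fingerprint | backend / folding | Morgan, radius 2, 1024 bits | folding beyond ~1000 bits changes pair similarities negligibly (checked in tests at 1024 vs 16384) |
| threshold | active/inactive cutoff | 0.1 | strict: active iff score > threshold |

`k` and `y` are partially redundant — both control how far into structure
space the estimate reaches — so distinct `(k, y)` combinations often score
identically; the grid table reports all of them and ties are listed
explicitly.

## Numerical choices

- **Log-domain power mean.** With exponents up to 50, `A^x S^y`
  under/overflows in doubles. The estimator computes
  `exp((logsumexp(x·log A_j + y·log S_j) − logsumexp(y·log S_j))/x)`.
  Zero-activity neighbors are handled by mass accounting: `0^x = 0` for
  `x > 0`, so they vanish from the numerator while their similarity weight
  stays in the denominator. Tests compare against a 60-digit
  arbitrary-precision oracle at `x = y = 50` (agreement ≤ 1e-8) and a naive
  float transcription at moderate exponents (≤ 1e-10).
- **`x = 0`** is defined as the `y`-weighted geometric mean, the analytic
  limit of the power mean, because tuning grids include 0.0.
- **Conventions:** `0^0 = 1`, so `y = 0` keeps zero-similarity neighbors at
  unit weight (pure power mean); for `y > 0` they carry zero weight. If
  *every* neighbor weight vanishes, the estimator falls back to the
  unweighted mean (gknn) or the most similar neighbor (exponential) with a
  runtime warning. Tanimoto of two all-zero fingerprints is 1.0 (identical
  emptiness), all-zero vs nonzero 0.0, avoiding 0/0.
- **Exponential weights** are shifted by the per-row maximum log-weight
  before exponentiation, so underflow can only occur when all similarities
  are exactly zero.
- **Ties** in neighbor similarity are broken by dataset order (stable
  argsort); predictions are therefore bit-reproducible across runs.
- **Final clipping** bounds each estimate to the [min, max] of the neighbor
  activities that carried weight, guarding against last-bit float
  excursions.

## Metrics and tuning

Truth and estimates are binarized at the same strict threshold (default
0.1). Seven metrics are reported: sensitivity, specificity, balanced
accuracy, accuracy, precision, NPV, and ROC AUC; AUC is computed from the
*continuous* estimates against binarized truth (binarized predictions
would make it degenerate) through scikit-learn, which implements the
Mann–Whitney convention with ties at 0.5 — the O(n²) pair count is kept as
an independent oracle in the tests. Zero-denominator ratios are NaN and
flagged, never silently zero; the composite score
`balanced accuracy × accuracy × AUC` is NaN whenever a factor is, and
undefined scores rank below all defined ones in the grid table.

Leave-one-out cross-validation predicts each training chemical from all
the others. The self-similarity matrix and per-chemical sorted neighbor
lists are computed once and shared across held-out chemicals and grid
points, reducing each grid point to a top-`k` slice plus a vectorized
estimator call; equality with a naive retrain-per-chemical loop is
asserted to 1e-10 in the tests. The full default grid realizes
10 × 17 × 17 = 2890 gknn combinations; the realized count is always
reported. Families that ignore `x` and/or `y` are swept only over their
relevant axes.

## Training-set curation

Scores in the open interval `(0.01, 0.1)` sit just above the activity
cutoff where false positives concentrate and are removed from training
sets; the bounds are configurable and boundary values are retained (the
interval is read as open since the thresholds themselves should remain
valid scores). Multi-source scores are averaged with a plain arithmetic
mean. Evaluation subsets can require `> N` sources per chemical with an
≥ 80 % majority call; chemicals with no recorded sources are excluded
rather than defaulted.

## Chemical-space projection

The low-dimensional picture of a chemical set comes from the
eigendecomposition of the double-centered self-similarity matrix (the
kernel-PCA convention) rather than covariance PCA on raw fingerprint bits:
the similarity route is independent of fingerprint length and works for
abstract fixtures that have no bit vectors at all. Out-of-sample chemicals
are projected from their similarity rows to the training set. Tanimoto
matrices need not be positive semidefinite; small negative tail
eigenvalues are reported as computed but clipped to zero when scaling
coordinates.

## Synthetic data

The generator emulates curated receptor-activity sets: continuous scores
on `[0, 1]`, heavy class imbalance (steerable via `n_actives`, e.g. 9 or
80 actives), multi-source call records with a mix of consistent and
inconsistent chemicals.

- *smooth*: activity is a clipped linear ramp (Lipschitz constant
  `lipschitz`, default 2) in the similarity to a seed chemical. Because
  Jaccard distance `1 − S` is a metric, the reverse triangle inequality
  gives `|A_i − A_j| ≤ L (1 − S_ij)` — every finite SALI value is bounded
  by `L` *by construction*. A deterministic 1e-9-per-position ramp breaks
  exact similarity ties so the active count is exact; it perturbs the SALI
  bound by a negligible `O(n · 1e-9 / (1 − S))` term.
- *cliff*: the smooth construction plus one designated pair with
  `S ∈ [0.8, 1)` whose activities are forced to 0.9 / 0.05, creating a
  SALI ≥ 4 cliff (0.8/(1−0.8) = 4 is the natural detection threshold for
  such pairs).
- *random*: i.i.d. uniform activities, a maximally rugged landscape.

`real_smiles` mode enumerates a deterministic scaffold × chain × terminal-
group roster of valid structures (folded-fingerprint duplicates removed)
and computes true Morgan similarities; `abstract_matrix` mode embeds
chemicals on a line segment with `S_ij = 1 − |u_i − u_j|`, which is exact,
fast, and hand-checkable. What the synthetic sets do **not** emulate:
realistic pharmacology (no docking or pharmacophores), assay noise
structure, or the scale and chemical diversity of real screening
libraries — passing tests demonstrate the correctness of the machinery and
its qualitative behavior under controlled landscapes, not real-world
predictive accuracy.

Problem sizes in the test and acceptance runs (60–200 chemicals, reduced
grids of ~36 combinations) were chosen so the full pipeline — similarity
matrices, LOO sweeps, landscape analyses — runs in seconds while still
exhibiting the imbalance and ruggedness regimes of interest.

## Known limitations

- No feature selection or descriptor engineering: conventional
  fingerprints and Tanimoto similarity only.
- Scores must already be on `[0, 1]`; converting raw potency values (e.g.
  AC50) to that scale is dataset-specific and out of scope.
- Path-based hashed fingerprints stand in for other full-fingerprint
  backends; the `FingerprintConfig` interface is the extension point for
  additional toolkits.
- Confidence `q` is a proxy, not a calibrated probability; no confidence
  intervals on metrics.
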