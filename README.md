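# gknnqsar

Quantitative structure–activity relationship (QSAR) modelling with a
**generalized k-nearest-neighbor (GkNN)** estimator, for cheminformatics
practitioners who need activity predictions, activity-cliff diagnostics, and
principled hyperparameter tuning on small-to-medium chemical sets.

## The model

Chemicals are described by binary fingerprints (Morgan/ECFP-like by default)
and compared with Tanimoto similarity `S ∈ [0, 1]`. A query chemical's
continuous activity score `A ∈ [0, 1]` (0 = inactive, 1 = active) is
estimated from its `k` most similar training chemicals as a
similarity-weighted power mean:

```
Â_i = ( Σ_j A_j^x · S_ij^y  /  Σ_j S_ij^y )^(1/x)
```

The exponents tune non-linearity in the two spaces: `x` in activity space
(`x = 1` → weighted arithmetic mean, `x → 0` → weighted geometric mean,
large `x` → the most active neighbor dominates) and `y` in structure space
(`y = 0` → all neighbors equal, large `y` → only the closest neighbor
counts). The classical kNN variants — arithmetic, geometric, and
exponential-distance-weighted (`w_j = exp(−x·d_ij)`, `d_ij = 1/S_ij − 1`) —
are included as reference models. Each prediction carries a confidence
`q_i = max_j S_ij`, the similarity to the nearest training chemical, which
serves as an applicability-domain proxy.

Landscape ruggedness is quantified by the structure–activity landscape
index `SALI_ij = |A_i − A_j| / (1 − S_ij)`; large values flag *activity
cliffs* (structurally similar chemicals with very different activities),
which are exactly the places where similarity-based prediction fails.

Parameters are selected by leave-one-out cross-validation over a
`(k, x, y)` grid, ranking parameterizations by the composite score
`balanced accuracy × accuracy × ROC AUC` after binarizing scores at a 0.1
activity cutoff.

## Worked example

Every capability has a short narrative script under `examples/`. Tuning on a
scarce-actives set (`examples/04_tune_parameters.py`):

```text
evaluated 36 (k, x, y) combinations
top 5 parameterizations:
  family   k    x    y  balanced_accuracy   roc_auc     score
0   gknn  10  3.0  0.0           0.816742  0.844920  0.638325
1   gknn  10  3.0  1.0           0.816742  0.844920  0.638325
2   gknn  10  3.0  5.0           0.816742  0.844508  0.638015
3   gknn   5  3.0  0.0           0.742493  0.857672  0.585870
4   gknn   5  3.0  1.0           0.742493  0.857672  0.585870
baseline (k=1, x=1, y=0) score: 0.4832
best score:                     0.6383
```

With only 9 actives among 200 chemicals and noisy labels, the tuned
non-linear power mean (`k = 10, x = 3`) clearly beats the plain
single-nearest-neighbor baseline: averaging over several
similarity-weighted neighbors suppresses label noise that `k = 1` copies
verbatim, and `x > 1` counteracts the dilution of the rare actives. The
landscape example prints `max SALI = 1.06` for a smooth synthetic set
versus `9.35` for one with a built-in cliff — the diagnostic separates the
two regimes cleanly.

A thin CLI wraps the same library functions:

```bash
gknn generate --n 100 --landscape cliff --out run/
gknn landscape --train run/dataset.csv --out run/
gknn tune --train run/dataset.csv --out run/
gknn predict --train run/dataset.csv --query new.csv --k 10 -x 1.5 -y 3 --out run/
gknn evaluate --truth new.csv --pred run/predictions.csv --out run/
```

Real-world workflows read training tables as CSV/TSV (configurable column
names) or SDF; activity scores must already be on the `[0, 1]` scale.
Training-set curation (removal of the uncertain score band `(0.01, 0.1)`),
multi-source score averaging, and consistency filtering (`> N` sources
with an ≥ 80 % majority call) are provided in `gknnqsar.chemio`.

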