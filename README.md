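# sweatvoc

Sweat-volatilomics discrimination pipeline: from vectorized GC×GC−MS
descriptor tables to pre/post-surgery classification, descriptor-level SHAP
importance, probe-variable relevance selection, and cross-dataset stability
comparison.

## The problem

Comprehensive two-dimensional gas chromatography–mass spectrometry
(GC×GC−MS) screens of sweat reduce each chromatogram to a fixed-length
vector: one non-negative peak area per compound of a screening library
(761 *descriptors* by default; a descriptor absent from a chromatogram has
area 0). Cohorts of breast-cancer patients sampled before ("pre", sick) and
after ("post", healthy) tumor-removing surgery produce such vectors from two
body sites (breast and hand), with up to 4 technical replicates per sampling
event and a systematic batch shift whenever a GC column is replaced.

The analysis question is twofold: **can a classifier separate pre from post
status from the descriptor vector**, and **which descriptors carry that
separation** beyond what a pure-noise feature would achieve?

## The method

For a dataset of measurements `x ∈ R^p_{≥0}` with labels y ∈ {pre, post}:

1. **Log transform** — `a ↦ ln(1 + a)` (zeros stay zero).
2. **Univariate screening** — per descriptor, a two-sided Mann–Whitney U
   test of pre vs post; descriptors ranked by ascending p (no multiplicity
   correction); the significant (p < α) set feeds a PCA for visualization.
3. **Classification** — L2-penalized logistic regression on the top-N
   ranked descriptors, standardized on the learning rows. Class imbalance is
   corrected with SMOTE (convex interpolation between minority nearest
   neighbors) on the learning rows only. Hyperparameters (C, N) are chosen
   by group-aware leave-one-out cross-validation of the F1-weighted score;
   among tied cells the lowest-complexity model (smallest N, then smallest
   C) wins. All splits keep the technical replicates of one
   (subject, status) sampling together.
4. **Attribution** — for the linear decision value `f(x) = w·x + b`, Shapley
   attributions are exact: `φ_ij = w_j (x_ij − x̄_j)`, so
   `Σ_j φ_ij = f(x_i) − f(x̄)`. Descriptor importance is the mean |φ|.
5. **Relevance (probe-variable method)** — append an i.i.d. standard-normal
   probe column, refit at the same C, record the probe's importance rank;
   repeat R times to estimate the probe-rank CDF `F(r)`. For risk δ, keep
   the descriptors whose reference rank is at most
   `r_δ = max{r : F(r) ≤ δ}` — the chance that a pure-noise feature beats
   them is at most δ.
6. **Stability** — Jaccard index |A∩B|/|A∪B| of retained sets between body
   sites, batches or runs.

Patient measurements are not distributed with the package; a synthetic
cohort generator (`sweatvoc.synthetic`) reproduces the statistical structure
the analysis assumes — zero-inflated log-normal areas, U-shaped occurrence
frequencies, per-measurement non-zero counts in the observed envelopes
(77–242 breast, 82–348 hand), area sums spanning ~2 orders of magnitude,
batch shifts, correlated technical replicates, and a planted pre/post effect
on a known descriptor subset — so every stage is testable against ground
truth.

## Worked example

```python
import numpy as np
import sweatvoc as sv

breast, hand = sv.make_study_pair(seed=7)

logged = sv.log_transform(breast)
train, test = sv.split_train_test(logged, np.arange(logged.n), 0.3, seed=7)
grid = sv.grid_search(logged, train, c_grid=[0.003162, 0.01, 0.1],
                      n_grid=[20, 40, 80], seed=7)
holdout = sv.evaluate_holdout(logged, train, test,
                              grid.best_C, grid.best_N, seed=7)

standardized = sv.apply_scaler(logged, sv.fit_scaler(logged, train))
X = standardized.areas[train][:, logged.library.indices(holdout.subset)]
probe = sv.probe_relevance(X, logged.labels()[train], C=grid.best_C,
                           R=2000, seed=7, descriptor_ids=holdout.subset)
```

prints (via the obvious `print` calls):

```
breast measurements: 136 | hand: 136
breast non-zero descriptors per measurement: 77 - 242
best C=0.003162, N=20, LOO CV score=0.905
holdout F1-weighted=0.949, sensitivity=1.00, specificity=0.88
probe rank range: 3 - 21
retained descriptors: {0.05: 18, 0.1: 19, 0.2: 20}
```

Reading: the grid search settles on a strongly regularized model over the
20 best-ranked descriptors, scoring 0.905 in leave-one-out CV; on the
untouched test groups it reaches F1 0.949 with every pre-surgery sample
recognized (sensitivity 1.00). Over 2000 probe realizations the noise probe
ranks between 3rd and 21st among the 21 columns; at risk δ = 5%, 18 of the
20 descriptors are judged more relevant than chance.

The same workflow is available from the shell:

```sh
sweatvoc simulate --seed 7 --out-dir sim/
sweatvoc run --measurements sim/measurements.csv --library sim/library.csv \
             --seed 7 --out-dir out/
sweatvoc compare out/batch_column2_retained_delta05.csv other/retained.csv
```

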