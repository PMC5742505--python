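# kin — K important neighbors

Binary classification for high-dimensional, low-sample-size data — the
regime of gene-expression panels, metabolomics and clinical risk scores,
where a few dozen training samples carry hundreds of candidate features
and plain nearest-neighbor methods drown in noise dimensions (distance
concentration, hubness).

## The method

KIN couples a sparse penalized regression to a nearest-neighbor vote:

1. **Feature screening.** A SCAD-penalized logistic regression
   (smoothly clipped absolute deviation penalty, shape constant a = 3.7,
   strength λ chosen by 5-fold cross-validation) is fit on the training
   data.  The SCAD penalty sets truly-uninformative coefficients to exact
   zeros while leaving large coefficients essentially unshrunk (the
   "oracle" behaviour of nonconvex penalties).
2. **Contribution weights.**  Each feature receives weight
   `w_j = |β_j| / Σ_j |β_j|`, so selected features contribute in
   proportion to their coefficient magnitude and noise features get
   weight zero.
3. **Weighted dissimilarity.**
   `d(x_a, x_b) = sqrt( Σ_j w_j (x_aj − x_bj)² )` — a weighted Euclidean
   distance in which zero-weight features provably cannot affect any
   prediction.
4. **Voting.**  A query takes the majority label of its k smallest-
   dissimilarity neighbors; k (even and odd values up to √n_train) is
   chosen by 5-fold cross-validation.  An even-k split vote goes to the
   class whose tied neighbors have the smaller summed dissimilarity.

The package also ships the plain-KNN baseline (odd k, Minkowski
distance), the correlated-Gaussian simulation framework used to study the
method, and the evaluation statistics: prevalence-weighted
misclassification rate (MC), false-positive feature count (#FP), true
contribution (TC — weight mass on truly-informative features), PAMA and
P95 winner statistics.

## Worked example

```python
import numpy as np
from kin import ScenarioSpec, simulate_dataset, fit_kin, predict_kin, misclassification_rate

# 100 features, 2 informative (coefficients 1 and 2), AR(1) correlation 0.8
spec = ScenarioSpec(p=100, sparsity=0.98, n=100, class1_ratio=0.5, rho=0.8, seed=1)
ds = simulate_dataset(spec, rep=0)
Xtr, ytr = ds.train
Xte, yte = ds.test

model = fit_kin(Xtr, ytr, seed=1)
print("selected features:", model.weights.support)
print("weights:", np.round(model.weights.w[model.weights.support], 3))
print("k:", model.k_selected)
print("test MC:", round(misclassification_rate(yte, predict_kin(model, Xte)), 3))
```

prints

```
selected features: [1]
weights: [1.]
k: 3
test MC: 0.2
```

With only 40 training samples, the penalized fit kept feature 1 — the
stronger of the two informative features (generating coefficient 2) —
and no noise feature; its correlated weaker partner (feature 0,
coefficient 1, correlation 0.8 with feature 1) is absorbed rather than
selected on this replicate.  Voting over k = 3 neighbors in the resulting
one-dimensional weighted dissimilarity misclassifies 20% of the 60
held-out samples, against 31.7% for plain KNN on the same replicate.

The same pipeline is available from the shell:

```bash
kin fit --input data.csv --label y --seed 1 --out model.json
kin predict --model model.json --input new.csv --out preds.csv
kin simulate --grid grid.yaml --out results/
kin report --results results/ --style table2
```

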