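# Methods

## Model

KIN classifies a query point by majority vote among its k nearest training
points under the contribution-weighted Euclidean dissimilarity

    d(x_a, x_b) = ( Σ_j w_j (x_aj − x_bj)² )^{1/2},
    w_j = |β̂_j| / Σ_j |β̂_j|,

where β̂ is the coefficient vector of a SCAD-penalized logistic regression
fit to the training data.  The weights are taken on the absolute
coefficients: a signed reading would make the radicand of the
dissimilarity negative whenever a selected coefficient is negative, so the
magnitude is the only coherent interpretation of "contribution".  Because
exact-zero coefficients produce exact-zero weights, features discarded by
the penalized fit cannot influence any prediction — the method performs
dimension reduction and classification in a single construct.

On an even-k split vote the query is assigned to the class whose tied
neighbors have the smaller summed dissimilarity; an exact tie of the two
sums (a measure-zero event) resolves deterministically to class 0.  Exact
distance ties at the k-th neighbor resolve by training-row index (stable
sort).

## Penalized fit

The SCAD penalty with shape constant a = 3.7 is

    p_λ(β) = λ|β|                                |β| ≤ λ
           = (2aλ|β| − β² − λ²) / (2(a−1))       λ < |β| ≤ aλ
           = λ²(a+1)/2                           |β| > aλ,

continuous, symmetric, nondecreasing in |β| and flat beyond aλ — small
coefficients are soft-thresholded to zero, large ones are left unshrunk.
The fit minimizes the mean Bernoulli negative log-likelihood plus
Σ_j p_λ(β_j), intercept unpenalized, feature columns standardized to mean
0 / sd 1 with training statistics (the penalty is scale-dependent, and the
same statistics standardize test data at prediction time).

**Solver.**  Majorize–minimize: the logistic loss is upper-bounded by a
quadratic with the worst-case Bernoulli curvature 1/4, and the penalized
weighted-least-squares surrogate is solved by coordinate descent where
every coordinate update is the exact scalar SCAD proximal operator
(`scad_threshold`).  Because the surrogate is a global majorizer and the
nonconvex penalty is handled exactly per coordinate, the penalized
objective is monotone non-increasing across outer iterations — a guarantee
a Newton-style inner loop would not give without safeguards.  Warm starts
along a decreasing λ path keep the nonconvex problem on the
well-understood solution branch.

Convergence is declared when the relative objective decrease falls below
`tol = 1e-6` with settled coefficients, with two principled early exits:
mean negative log-likelihood below 1e-4 (saturated fit), or an objective
stalled at `tol` while coefficients still drift.  The latter occurs
whenever the training data are separated at small λ: the SCAD penalty is
bounded, so a separating coefficient direction can grow without bound
while the objective change vanishes.  Coefficients with magnitude below
1e-10 are stored as exact zeros so the support is well defined.

**λ selection.**  A 50-point geometric grid from λ_max (the smallest
strength giving the all-zero model, `max_j |X_j'(y − ȳ)|/n`) down to
0.01·λ_max, evaluated by 5-fold cross-validation.  Two choices here were
genuinely open and were settled as follows:

- *CV loss:* the class-proportion-weighted misclassification rate of the
  plug-in rule (the same loss used everywhere else in the pipeline, and
  the quantity the method is evaluated on), not binomial deviance.
  Deviance selection is smoother but measurably more conservative: it
  produces visibly sparser supports than the published behaviour of the
  method.  Deviance remains available (`PenaltyConfig(cv_loss="deviance")`).
- *Folds:* a plain random division into equal parts, matching the
  method's description of cross-validation, rather than stratified folds.
  A fold whose training part contains one class is skipped in the CV
  average; this matters only in the strongly unbalanced small-n settings.
  Stratified folds are available behind a flag.

Ties along the CV curve resolve toward the larger λ (the sparser model).
If the selected model is empty, KIN degrades to predicting the training
majority class with a warning — an unweighted fallback distance would
contradict the method's premise.

## Neighbor count

k is chosen from {1, …, ⌊√n_train⌋}, even and odd, by 5-fold
cross-validation on the weighted misclassification rate, ties toward the
smallest k.  The plain-KNN baseline uses the identical machinery
restricted to odd k (which cannot tie) and the unweighted Euclidean
distance (Minkowski order 2 by default, configurable), so a KIN-vs-KNN
comparison isolates the dissimilarity measure.

## Simulation framework

Each scenario draws X with every feature marginally standard normal and
AR(1) dependence corr(x_j, x_j') = ρ^{|j−j'|} (generated by the O(np)
autoregressive recursion, not a Cholesky factor), and labels
y ~ Bernoulli(expit(β₀ + X'β)).  The true β places alternating values
1, 2, 1, 2, … on the first s = round((1−sparsity)·p) features — adjacent
placement interacts with the AR(1) correlation and is the configuration
the evaluation statistics assume.  The study grid crosses
p ∈ {100, 300, 500}, sparsity ∈ {0.90, 0.95, 0.98}, n ∈ {100, 200},
class-0 share ∈ {0.5, 0.8} and ρ ∈ {0.4, 0.8}; every dataset splits
40/60 into training and testing, unstratified, with a redraw if the
training part is single-class.

Unbalanced classes are induced by calibrating β₀ so that
E[expit(β₀ + X'β)] equals the target class-1 share.  Since X'β is exactly
N(0, β'Σβ) under the Gaussian design, the calibration reduces to
root-finding on a one-dimensional Monte-Carlo estimate (10⁵ draws, fixed
internal seed), accurate to well under 0.01 in the realized class share.

Every replicate is a pure function of (scenario seed, replicate index).
Comparator classifiers are deliberately off-the-shelf: random forest with
500 trees, and a linear-kernel SVM with cost tuned over [0.001, 5] by
stratified CV.

**What the generator does not emulate:** real measurement noise is rarely
Gaussian or AR(1)-correlated, real effects are not tidily alternating
1s and 2s, and real class imbalance comes with covariate shift.  Passing
the simulation checks shows the pipeline reproduces the method's
behaviour under its stated statistical model, not that the accuracy
figures transfer to any particular real dataset.

## Evaluation statistics

- **MC** — Σ_y π_y m_y/n_y with π_y the class share of the evaluated
  sample; equal to the plain error fraction under this weighting (the
  formula is kept explicit so fixed priors can be substituted).
- **#FP** — selected features outside the true signal set.
- **TC** — Σ of dissimilarity weights over the true signal features; the
  scenario summaries report both the all-replicates average (null models
  contribute 0) and the average over non-null replicates, since published
  averages rarely state the convention.
- **PAMA / P95** — per-classifier fraction of scenarios won outright
  (ties credit all) / within 95% of the row-best accuracy (boundary
  inclusive).

## Problem sizes

The original study averaged 250 replicates per scenario over 72
scenarios.  The replication suite and the acceptance script use 20–50
replicates per scenario (50 for single-cell averages, 25 for the
24-scenario p=100 block, 20 for the in-suite aggregate block), sizes at
which the Monte-Carlo standard error of a scenario-mean MC is roughly one
percentage point and the documented stochastic tolerances absorb the
noise.

## Known limitations

- Binary classification only; no multiclass extension.
- The SCAD solver in this package selects noise features noticeably less
  often than the published study reports (mean #FP well under 1 per
  p=100 scenario versus ≈ 2), with correspondingly slightly better
  accuracy; the feature-selection side of a replication is therefore
  *cleaner* than the original, not bit-identical to it.
- Neighbor search is exact and O(n²); appropriate for the small-n regime
  the method targets, not for large training sets.
- Missing values are rejected, not imputed.
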