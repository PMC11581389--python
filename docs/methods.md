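# Methods

`clinimage` implements a tabular-to-image transfer-learning pipeline for
predicting invasive disease events (IDE — recurrence, distant metastasis,
contralateral or second tumour) within 5 or 10 years of a first invasive
breast-cancer diagnosis, from 28 routine clinical/histopathological features.
This note records the model, its assumptions, the parameters that matter, and
the choices made where the design was genuinely open.

## Cohort model and encoding

A cohort is an `n x 28` matrix over a fixed feature catalogue (demographics,
histology, receptor status, nodal involvement, surgery and adjuvant-treatment
variables) with a binary IDE label at a fixed horizon. Ordinal features
(grade G1–G3, tumour size T1a–T4, nodal status N0–N3, HER2/neu score 0–3,
intraductal component) are coded as consecutive integers in clinical order;
nominal features in catalogue order. Because every downstream consumer sees
only min-max-normalised values, any strictly increasing coding of an ordinal
is equivalent; the nominal order is recorded in the schema for
reproducibility, not because it carries meaning.

Missing cells are imputed by proximity: an incomplete patient copies each
missing cell from the fully observed reference patient at minimum Euclidean
distance over the observed features, computed after per-feature min-max
scaling fitted on the reference cohort. Donors are restricted to complete
records so a donor value always exists; ties break to the lowest donor row
index. The reference cohort is a parameter (training data by default) rather
than a fixed dataset.

Hold-out splitting is stratified per class with round-half-up counts
(`floor(f * n_class + 0.5)`), which reproduces printed splits such as
251/375 positives/negatives at 80% → 201 + 300 train, 50 + 75 test.

## Synthetic cohorts

The real cohort is private, so the generator emulates its published marginal
summaries. Continuous features (age, ER%, PgR%, ki67%, eradicated and
metastatic lymph nodes) are drawn from a piecewise-linear quantile function
through (0, lo), (0.25, q1), (0.5, median), (0.75, q3), (1, hi), where the
median/quartiles are the published values and the domain endpoints lo/hi are
package choices (age [25, 92] years; percentages [0, 100]; eradicated nodes
[0, 45]; metastatic nodes [0, 30]) fixed once at plausible clinical extremes.
Categorical features are sampled from the published level frequencies with
missing-level counts excluded from the denominator. Default class sizes are
the 5-year cohort's 168 IDE / 528 controls.

The class-conditional signal is a knob, not an emulated quantity — the real
class-conditional distributions were never characterised:

* `simulate_cohort` shifts a positive-class continuous feature's quantile
  curve by `effect_size x IQR` (re-clipped to the domain) and applies an
  additive zero-sum probability tilt toward higher levels for categorical
  features; a tilt that would push any level probability outside [0, 1] is a
  configuration error.
* `simulate_separable_cohort` plants a known informative subset. Continuous
  features fill the subset first (an IQR shift is exactly calibrated for
  rank-based recovery); categorical slots use exponential tilting
  (`p_k ∝ p_k exp(delta z_k)` with standardised level index `z_k`), which is
  well-defined for any delta. The ground-truth set is returned for recovery
  experiments.

Missingness is completely at random at a single configurable rate, default 0
(it is a controllable test knob; the published per-feature missing rates are
1–3% and are not emulated). The generator reproduces marginals, not the real
cohort's joint dependencies: a green downstream test establishes that the
pipeline machinery behaves correctly under the stated marginals and signal
model, not that the published discrimination is attainable.

## Image transformation

The training matrix is min-max normalised per feature (test values are
clipped into [0, 1]; features constant in training map to 0, i.e.
background). Each of the 28 features is then one point in patient-space (a
column of the normalised matrix); a Gaussian-kernel PCA of these 28 points —
double-centered kernel, top-2 eigenvectors scaled by sqrt(eigenvalue) —
gives 2D feature coordinates. The kernel width defaults to the median
pairwise distance among feature points (the median heuristic, scale-free),
configurable. Eigenvector sign is fixed by making each component's
largest-magnitude entry positive, so layouts are reproducible.

The convex hull (monotone chain) and the minimum-area enclosing rectangle
(rotating calipers: the optimum is flush with a hull edge; angle normalised
to [0°, 90°), area ties break to the smaller angle) frame the point cloud.
Coordinates are rotated so the rectangle's longer side is horizontal
(landscape), then affinely mapped onto a `rows x cols` pixel grid — default
50 x 50, ample for 28 features — with pixel = floor of the scaled
coordinate, boundary points clamped inside, 0-based indices, origin top-left.
Features sharing a pixel form a collision group and contribute the
arithmetic mean of their values (value-preserving and order-independent).
A patient's image is zero background with each feature's pixel set to its
normalised value. The whole chain is deterministic and is fitted on training
patients only; the frozen layout, including normalisation bounds, is reused
verbatim on unseen patients.

## Deep feature extraction

Images are bilinearly resized to 227 x 227, replicated to 3 identical
channels, and passed through the fixed AlexNet front end (conv1 96@11x11
stride 4, ReLU, maxpool 3x3 stride 2; conv2 256@5x5 pad 2, ReLU, maxpool 3x3
stride 2). The pool2 output (13 x 13 x 256) is flattened channel-major into
43,264 features per patient. The network is a frozen feature extractor, so
the forward pass is implemented directly in numpy (batched im2col + BLAS
matmul); no deep-learning runtime is needed. Weights come from a seeded
He-normal initialiser with zero biases, making extraction fully reproducible
offline; ImageNet-pretrained weights would require a download and therefore
raise an explicit error here. The pipeline's geometry and statistics are
weight-agnostic; absolute discrimination levels under random versus
pretrained weights may differ. Inputs are fed in [0, 1] without further
standardisation under random weights.

## Feature selection and classifier

Per deep feature, a two-sided Wilcoxon rank-sum test (exact for tiny
tie-free groups, normal approximation with tie correction otherwise)
compares the two classes; features with p < 0.005 (raw, strictly less, no
multiplicity adjustment) pass. A Random Forest (default 500 trees, sqrt(p)
features per split, seeded) ranks the survivors by impurity-decrease (Gini)
importance; features strictly above the median importance survive. Stability
selection repeats this screen on the fold-training portion of every fold of
every round of a repeated stratified k-fold partition (default 10 folds x 10
rounds) and keeps the intersection over all cycles.

Pool2 activations are highly collinear (neighbouring units share receptive
fields) and roughly 40% of columns are constant on typical layouts, so the
effective number of independent tests is far below 43,264: on signal-free
cohorts the filter passes almost nothing and the stability intersection is
empty essentially always. The default behaviour is the explicit
empty-selection error with per-cycle diagnostics; the pipeline estimator
also offers an opt-in fallback (the filter-passing set on the full training
data, or failing that the 50 smallest-p non-degenerate columns) so that
calibration experiments on null cohorts still produce a defined,
chance-level model.

The final classifier is a linear SVM (C = 1.0, no internal tuning) on the
stable features, standardised with training statistics. Decision scores are
signed distances to the hyperplane (up to the common ||w|| factor);
`predict` thresholds them at the Youden-optimal training threshold.

## Evaluation

AUC is the trapezoidal ROC area (ties half-credit), identical to the
rank-sum statistic U/(n1 n0). The operating point maximises Youden's
J = sensitivity + specificity − 1 over midpoints between distinct scores
plus ±∞, ties to the lowest threshold, `score >= threshold` predicting
positive; accuracy, sensitivity, specificity and precision are reported
there, all recomputable from the stored confusion counts. Cross-validation
performance is summarised by the median and quartiles of each metric over
the per-fold evaluations (each cycle refits the screen and SVM on the
fold-training portion).

Label-permutation significance reports both add-one estimators over N
permutations (default 100): the standard convention
`(#{null >= observed} + 1)/(N + 1)` — the default for decisions — and the
`<=`-counting convention `(#{null <= observed} + 1)/(N + 1)`, which a
well-separated model drives to exactly 1 and which is reported for
comparability with the convention some studies print. The default
permutation policy refits selection + SVM per permuted label vector on the
cached deep features (the image layout and extraction do not depend on
labels, so caching them is exact); a fast fixed-model rescore mode exists
and is labelled as such. Permutations drawing a degenerate single-class
partition or leaving no usable feature score at chance (0.5).

Patient-to-patient Spearman matrices (rho and t-approximation p-values,
computed as Pearson correlation of row ranks) are provided as the cohort
diagnostic; pairs involving a constant patient vector are NaN-flagged.

## Reproducibility and scale

One master seed deterministically derives per-stage seeds (simulate, split,
extractor, selection, permutation) via `SeedSequence([master, stage])`, all
below 2^31, so any stage is independently re-runnable. Everything outside
the seeded RNGs is deterministic, including the layout chain.

Test-suite and acceptance-script runs use reduced desk scales chosen for
runtime, fixed before measuring outcomes: cohorts of a few hundred patients,
stability schemes of 5–30 cycles instead of 100, forests of 150–300 trees.
The calibration bands and recovery thresholds they assert are not adjusted.
Known limitations: random (not pretrained) extractor weights; marginals-only
synthetic cohorts; no survival-time modelling (fixed-horizon dichotomy); no
alternative embeddings or backbones.
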