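# Methods

## Spectral model and reference library

A hyperspectral SRS stack is an H×W×C cube over an evenly spaced
Raman-shift axis covering the C–H stretch window, 2800–3050 cm⁻¹
inclusive (default C = 64 channels, ≈4 cm⁻¹ spacing; the channel count is
a free acquisition parameter and is configurable everywhere). The forward
model at a pixel is linear: `s = Xc + ε`, where the columns of `X` are the
four reference standards and `c ≥ 0` the biomolecular abundances.

References are harmonized by linear interpolation onto the analysis axis
(zero outside the source span — band intensity is not extrapolated) and
then scaled to unit Euclidean norm. l2 normalization makes the LASSO
penalty act evenly across components and gives the zero-solution threshold
a closed form (`λ_max = max_k |x_kᵀ s|`). A library must be genuinely
four-dimensional: assembly rejects stacks whose smallest singular value is
≤ 1e-6 after normalization.

The synthetic standards are sums of Gaussian bands at standard C–H
assignments — protein CH₃ ~2930, nucleic acid ~2955, saturated-lipid CH₂
~2850 with a 2880 shoulder, unsaturated lipid ~2850 plus the olefinic
=C–H ~3010 cm⁻¹. Widths and heights are idealized plumbing (see
`DEFAULT_PEAK_TABLES`), chosen so the four columns are distinguishable yet
realistically correlated: the default library's worst column cosines are
0.85 (saturated vs unsaturated lipid) and 0.72 (protein vs nucleic acid),
reproducing the cross-talk structure that makes C–H-window unmixing hard.
Baseline correction of measured standards is out of scope; CSV inputs are
assumed pre-baselined.

## LASSO unmixing

Per pixel the solver minimizes `½‖s − Xc‖² + λ‖c‖₁` subject to `c ≥ 0`
(signed fits behind `nonnegative=False`). Cyclic coordinate descent with
closed-form soft-threshold updates is run in fixed component order;
because `XᵀX` is only 4×4, every coordinate update is applied to all
pixels of an image simultaneously as a vectorized array operation, which
is what makes desk-scale stacks (10⁵–10⁶ pixels) take seconds. The
problem is convex, so the solution is independent of initialization; we
start from zero and stop when the largest coefficient change across all
pixels falls below `tol` (default 1e-8, max 1000 sweeps). There is no
spatial regularization — pixels are independent — and no dedicated
background component: empty pixels resolve to ≈0 coefficients.

The penalty default is λ = 1e-3, relative to unit-norm references and
order-unity abundances; at the simulator's noise level the per-component
recovery RMSE is ≈0.02, and a 5-fold channel-wise cross-validation helper
(`select_lambda`) is provided for data where the noise scale is unknown.
Numerical tie-breaks: convergence is declared on coefficient change, not
objective change; the cyclic order is the library component order.

## Synthetic cohorts

The generator emulates dissociated single cells imaged on a dark
background. Cells are disks (no overlap; centers rejection-sampled, 1000
attempts before a placement error) with log-normal radii and log-normal
per-component abundances: log-normality keeps both strictly positive and
right-skewed, the usual shape of biological intensity variation. An
optional per-cell multiplicative factor (CV 0.10, on by default) mimics
inter-sample intensity variation; it is folded into the recorded
ground-truth abundance, so truth tables state exactly what was rendered.
Channel noise is additive i.i.d. Gaussian (σ = 0.02 by default, ≈10:1
peak SNR for a typical cell), the shot-noise-limited approximation for
SRS detection.

The class-effect table (`data/class_profiles.yaml`) fixes, per class, the
mean 4-vector of abundances, radius, and CVs (0.12 abundance, 0.06
radius). Magnitudes were set once to encode the qualitative group
contrasts the platform is meant to detect — AML-M2/M3/M4 above
granulocytes in protein and both lipids but below in nucleic acid; AML-M5
above monocytes in all four; both ALL classes below every AML subtype in
both lipids; Ph⁺ above Ph⁻ in unsaturated lipid; M3/M5 the unsaturated/
saturated extremes among AML — and to place the six leukemia classes at a
mutual separability where the pipeline lands in the high-80s percent
cross-validated accuracy, the regime reported for patient-derived cells.
They are simulator parameters, not measurements.

What the simulator deliberately omits: subcellular texture (nucleus vs
cytoplasm), point-spread blur, touching cells, per-channel (colored)
noise, and baseline drift. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
performance on real instrument data, where segmentation and cross-talk
are harder.

## Phenotyping

Segmentation operates on the sum of the four chemical maps (the
highest-SNR single image): Otsu threshold by default (a constant image
yields an empty mask, not an error), hole filling, 8-connected labeling,
removal of components below `min_area` (default 30 px), and relabeling in
raster order of centroids. The phenotype is the fixed 5-feature vector
(area, protein, nucleic acid, saturated lipid, unsaturated lipid). Content
features are integrated totals (sum of coefficients over the mask) so that
composition and cell size jointly carry signal, matching the joint use of
area and content downstream; per-pixel means are available via
`aggregate="mean"`. Area is in pixels, or µm² when a pixel size is given.

## OPLS-DA

Implemented from first principles (no chemometrics dependency). Features
are autoscaled (mean 0, sample-s.d. 1; constant columns map to zero).
Class labels become a one-hot dummy matrix `Y`; fitting proceeds in two
stages:

1. **Orthogonal filtering** (`A_ortho` rounds): the dominant PLS2 weight
   `w` of the current (X, Y_c) is found by NIPALS; the loading `p` of its
   score is stripped of its component along `w`; the result is then
   projected onto the null space of `Y_cᵀX`. That last constraint is this
   implementation's multi-class treatment: with a multi-column dummy
   matrix the classical single-y construction no longer guarantees
   score–class orthogonality, whereas the null-space projection makes every
   orthogonal score *exactly* uncorrelated (machine precision) with every
   class indicator while keeping `t_o = X w_o` and the deflation an
   orthogonal projection, so total sum of squares is conserved. A
   consequence: only `p − rank(Y_cᵀX)` such directions exist — none when
   K−1 ≥ p (e.g. six classes on five features). `A_ortho=None` resolves
   to one component when feasible, zero otherwise; explicit infeasible
   requests raise an error.
2. **Predictive fit**: `A` PLS2 components by NIPALS on the filtered X
   (deterministic start from the largest-variance Y-residual column,
   tolerance 1e-12 on the weight, max 1000 iterations — tight enough that
   the weights coincide with the exact dominant singular vectors), with
   both blocks deflated.

Prediction applies the stored scaler, removes orthogonal components,
projects, and takes `Ŷ = T Cᵀ + ȳ`; the label is the argmax column, ties
to the lowest class index. The default `A` is `min(K−1, p)` — full
discriminant rank — because an argmax over a rank-A `Ŷ` can only give all
K classes a winning region when A reaches K−1; two components remain the
convention for the scores *plot* (with a 1-predictive-component model the
second plot axis falls back to the first orthogonal score). Weight signs
are fixed so each column's largest element is positive, making fitted
models and plots reproducible. With `A_ortho=0` the model reduces exactly
to PLS2-DA, which the test suite verifies against an independent
SVD-based oracle.

PCA pre-reduction is not applied before OPLS-DA: with p = 5 features
there is no dimensionality to reduce.

## Evaluation

Rows of the confusion matrix are true classes, columns predicted.
Precision of a never-predicted class is undefined and reported as NaN
(never 0), excluded from any macro average. Cross-validation is stratified
k-fold (default k = 7), scaler and model refit inside every training
fold, predictions pooled; if the smallest class has fewer than k members,
k is reduced to that count with a logged warning. Both cross-validated
and resubstitution metrics are reported, clearly labeled — the honest
estimate is the former. Internals keep fractions; percent formatting is a
reporting-layer concern.

## Pipeline and reproducibility

`run_pipeline` chains simulate → unmix → phenotype → classify → evaluate.
One global seed is fanned out per stage through
`numpy.random.SeedSequence([seed, stage_index])`, so stages can be rerun
in isolation; every artifact is hashed into a run manifest. Segmented
cells are assigned class labels by greedy max-IoU matching against the
ground-truth masks; unmatched segments are dropped. Truth CSVs, feature
CSVs and metrics JSON are byte-identical across reruns with the same
config and seed (fixed float formatting, sorted JSON keys, no timestamps
in data artifacts).

Default problem sizes — 6 classes × 30 cells on 192×192×64 fields, 1000
pixels for solver recovery, 18 cells for the noiseless round-trip — run
the whole benchmark in seconds on one core while keeping class-mean
estimates stable; all are configuration values that scale up directly.

## Known limitations

- Cross-talk between the protein and nucleic-acid maps (and between the
  two lipid maps) is reduced but not removed by the L1 penalty; it is an
  acknowledged limitation of C–H-window unmixing generally.
- The classifier is linear in the five features; strongly non-linear
  class structure would need kernelized or tree-based alternatives.
- The simulator's homogeneous disks make segmentation nearly trivial;
  IoU-based accuracy figures do not transfer to textured real cells.
- OPLS-DA here fixes one global model for all classes (single dummy
  matrix); hierarchical schemes (e.g. AML-vs-ALL, then within-group) are
  composed by the caller, as in the AML/ALL grouping computed by
  `scripts/acceptance.py`.
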