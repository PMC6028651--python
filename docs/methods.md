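# Methods

This note records the modeling choices, conventions and numerical details
behind `petrad`, and what the synthetic-data experiments do and do not
demonstrate.

## Feature panel

**Discretization.** All histogram- and matrix-based features share one
convention: intensities inside the VOI are binned with a fixed **bin width
of 0.1 SUV**, bins anchored at the VOI minimum
(`level = floor((v - min)/0.1) + 1`). Min-anchoring makes every texture
feature invariant to adding a constant to the image, and re-anchoring per
wavelet subband handles the negative values high-pass subbands produce.
The same width is reused for first-order entropy/uniformity so the package
carries a single discretization convention.

**First-order (14).** Population moments (N in the denominator);
kurtosis is **non-excess** (Gaussian → 3). A constant VOI has variance
exactly 0 by definition; its skewness and kurtosis are undefined and are
returned as 0 with a `DegenerateFeatureWarning` rather than NaN, keeping
downstream feature matrices finite.

**Shape (8).** Volume is voxel count × voxel volume. Surface area defaults
to **exposed-voxel-face counting**, which is exactly hand-checkable (a
lone 4 mm voxel scores 6 × 16 mm²) but overestimates smooth surfaces by a
staircase factor — for a ball the factor tends to 3/2, so a digital ball's
face-count sphericity tends to 2/3, not 1. A marching-cubes mesh
estimator (`surface_area(..., method="mesh")`, Gaussian-smoothed indicator,
σ = 1 voxel) converges to the true area of smooth bodies and recovers
sphericity ≈ 1; it is an option, not the default, so the default pipeline
stays exactly reproducible by hand. Maximum 3D diameter scans surface
voxels only (the maximum over all foreground pairs is attained there).

**GLCM (23) / GLRLM (11).** Both matrices pool the **13 unique 3D
directions at Chebyshev distance 1** into a single matrix before feature
computation (per-direction averaging is the documented alternative; for
VOIs of a few hundred voxels pooling is more robust). GLCM distance is 1
voxel; the matrix is symmetrized and normalized. Logs are base 2 with
0·log 0 ≡ 0. Degenerate single-level matrices take their homogeneous
limits: contrast 0, energy 1, entropy 0, and **correlation 1** (a constant
region is perfectly correlated with its neighborhood). Sum variance is
centered on the sum average and difference variance on the difference
average. One naming collision is resolved by suffix: the co-occurrence
energy, entropy and variance are `energy_c`, `entropy_c`, `variance_c`,
distinct from their first-order namesakes. Run percentage is total runs
over VOI voxels, so it can exceed 1 when directions are pooled.

**Wavelet (384).** The decomposition is **undecimated**: each of the 8
subbands is the separable filtering of the grid with per-axis coiflet-1
low/high-pass decomposition filters (taps from PyWavelets), output at
voxel *i* summing taps over inputs *i+1 … i+R* (R = 6), with symmetric
reflection past the grid. Every subband keeps the grid shape, so the VOI
mask applies without resampling. Filtering runs on the VOI bounding box
padded by the filter length, so boxes smaller than the filter support are
handled and bounding-box edges do not leak artifacts into the mask.
Because the high-pass taps sum to zero only up to double-precision
rounding, a subband whose masked magnitude is below 1e-10 × the input
scale is snapped to exactly zero before features are computed — scale-free
statistics are meaningless on rounding dust. Per subband the 14 + 34
features above are recomputed (shape is geometry-only and not repeated):
8 × 48 = 384, names suffixed `_LLL` … `_HHH`.

## Selection, models, cross-validation

**AUC ranking.** Features are scored by the rank (Mann-Whitney) AUC
estimator, ties counting ½. Ranking uses the **oriented** AUC
max(AUC, 1−AUC) — features whose *low* values predict failure compete
equally — with the raw direction recorded; raw ranking is a flag. Ties
break lexicographically, making selection fully deterministic. The
consensus list orders features by cross-fold selection frequency, then
mean fold AUC, then name; it is a **reporting** artifact and is never fed
back into per-fold models (that would leak across folds). The
Mann-Whitney U test provides the p-values of the ranking report,
consistent with the AUC estimator.

**Families and grids.** The forest grows 100 trees, each on p ∈ {5,…,20}
bootstrap draws with q ∈ {5,…,50} candidate features per node; p and q
clamp to the fold's sample/feature counts and coincident grid points are
evaluated once. It is built as a thin bagging loop over CART trees, which
exposes the per-tree votes that define the risk score (vote fraction for
failure). Grid selection for the forest uses **out-of-bag accuracy** —
with p ≤ 20 draws from ~29 patients every patient is out-of-bag for most
trees, and OOB is the forest's native selection criterion, needing one fit
per grid point. SVM-RBF (C = 10^t, t ∈ [−5,5]; σ ∈ [0.1,1], γ = 1/(2σ²)),
ridge-regularized logistic regression and the ELM use 5-fold stratified
inner resampling on the training fold, scored by accuracy (the inner fold
count drops to the minority-class size on very small cohorts). Features
are standardized with training-fold mean/SD for the scale-sensitive
families; the forest sees raw features. The ELM draws its hidden layer as
the first h rows of one fixed random matrix per seed, so training error is
monotone in h, and solves the output weights by least squares over two
output nodes (control, failure).

**Decision rules.** Forest and logistic scores live in [0,1]; high risk
iff score **strictly** > 0.5. The SVM's signed distance is positive toward
control; distance ≤ 0 is high risk. The ELM calls high risk when the
failure node's output is at least the control node's. The logistic "risk
score" is the predicted probability (an unbounded linear predictor would
make the 0.5 threshold meaningless).

**LOOCV.** Each of n folds holds out one patient; ranking, grid search and
fitting see only the remaining n−1. For the "all" group the 8 clinical
covariates bypass the AUC screen and are always appended to the selected
radiomic features. Clinical covariates stay 8 numeric columns (tumor
location ordinal in anatomical order, gender binary) to preserve the
888-column contract. The best of the 4 × 5 cells is chosen by accuracy,
ties broken by sensitivity (the rarer class), then by the smaller feature
group.

## Survival

Kaplan-Meier uses the product-limit estimator; patients censored exactly
at an event time count as at risk for it. Confidence intervals are
**Greenwood variance on the linear scale, clipped to [0,1]** — the only
convention that can produce bounds like 100.0–100.0% or 0.0–40.2%;
log-log intervals cannot. When the curve reaches 0 the Greenwood term
degenerates and the variance is reported as 0. Readouts at a horizon are
right-continuous; a horizon past the last follow-up returns the last value
with an `extrapolated` flag. The log-rank test is the standard 1-df
observed-vs-expected statistic over pooled risk sets with the hypergeometric
variance; it is implemented in-package (a few dozen lines) because the
reporting needs per-group observed/expected counts, and is cross-checked
against lifelines in the tests. Median follow-up/PFS summaries are sample
medians of observed times, not curve medians.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes: n = 30
with 7 progressions / 23 controls; 32³ grids at 4 mm isotropic spacing;
ellipsoidal tumors with semi-axes drawn from 8–16 mm; background SUV 1.0.
Tumor voxels are a class mean (6.0 control / 7.0 progression) plus a
**spatially correlated Gaussian field** (white noise smoothed with a
Gaussian kernel of the class correlation length — 3 mm control, 9 mm
progression — standardized and scaled to amplitude 1.5 SUV) plus
independent N(0, 0.3²) voxel noise, clipped at 0. The mid-CRT volume
rescales the tumor's excess over background by a class response factor
(0.4 control, 0.85 progression) with fresh noise and the same propagated
contour. Clinical covariates are drawn from the cohort's marginal
distributions (26:4 gender, stage and dose tables) with **no outcome
dependence**, so synthetic predictive performance must come from the
images. PFS times are exponential with a class **hazard ratio of 8**,
early censoring with probability 0.2, and administrative censoring at each
patient's follow-up window (uniform 6–48 months). Local-control events
are observed for every progression — that is what the label means — and
absent for controls, censored at follow-up.

What passing tests show: the pipeline recovers planted mean/texture
differences through the full selection + LOOCV chain, without leaking the
held-out patient, and the survival machinery is calibrated (type-I error
≈ 5%, high power at hazard ratio 8). What they do not show: performance on
real PET data — the generator has no scanner point-spread function,
attenuation or reconstruction artifacts, no inter-patient anatomy, and its
effect sizes are free parameters, not calibrated to any clinical cohort.
A diluted risk-group PFS contrast is expected behavior here, because
synthetic PFS depends only on the class label while the median split
necessarily pulls some controls into the high-risk group.

## Problem sizes and runtime

Default experiments use the 30-patient cohort above; extracting 2 × 440
features for all 30 patients takes ~2 s, and one forest LOOCV with its
full grid ~40 s on one CPU. The repeated-seed signal-recovery experiment
uses 5 seeds; log-rank calibration uses 2000 null and 200 alternative
simulations at n = 15 + 15. Tests exercising oracle equivalence enumerate
VOIs up to 6³ voxels, where exhaustive pair/run counting is exact.

## Known limitations

Single-level wavelet decomposition only; no decimated variant; no
gray-level size-zone matrices; no Cox regression or competing risks; no
DICOM input (NIfTI only); injected dose is assumed decay-corrected to scan
time; no probability calibration of risk scores. Whether the original
analysis pooled or averaged texture directions, its GLCM distance, its
surface-area estimator and its first-order binning are not derivable from
the published material; the choices above are documented defaults, each
one flag away from its alternative where an alternative exists.
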