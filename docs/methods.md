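# Methods

## Variability maps

The per-participant measure of neural variability is the standard deviation
(population convention, divide by *n*) of each voxel's preprocessed
time-course. The preprocessing order is fixed: per-voxel least-squares
removal of nuisance signals (externally supplied WM/CSF averages and the
six realignment parameters; an intercept is always included), then an ideal
frequency-domain band-pass to 0.01–0.10 Hz (out-of-band Fourier bins zeroed,
DC always removed), then motion censoring, with only the surviving frames
entering the SD. Censored frames are *not* re-filtered; filtering before
scrubbing and scrubbing before filtering give measurably different maps, and
a regression test pins the implemented order.

The ideal filter makes the SD identical to the in-band amplitude of
low-frequency fluctuations: with the rfft convention,
`alff = sqrt(Σ_band w_k |F_k|²) / T` with `w_k = 2` for interior bins and 1
for DC/Nyquist, which equals the population SD of the band-passed series by
Parseval. A Butterworth or windowed filter would break this identity, which
is why the ideal filter is the default and only filter. MSSD (mean squared
successive difference over consecutive *kept* frame pairs) is provided as an
alternative variability metric; on band-limited data it rank-correlates with
the SD above 0.8.

**Framewise displacement.** FD is the backward-difference form: the sum of
absolute frame-to-frame changes of the three translations (mm) plus the
three rotations converted to arc length on a 50 mm sphere; `fd[0] = 0`. A
`literal=True` variant sums the absolute parameters without differencing,
for sensitivity checks only — the default is the differenced form because a
0.5 mm censoring threshold presumes it. Frames with FD strictly above
0.5 mm are censored together with 1 frame before and 2 after (window clipped
at run boundaries); runs retaining less than 240 s are excluded, with the
retained duration reported in the verdict. Whether mean FD (used later as a
confound) is computed before or after censoring is a free choice; it is
computed over all frames.

**Masking and scaling.** The analysis mask is gray-matter probability
≥ 0.5 (inclusive) minus an exclusion mask. Maps are z-scored across in-mask
voxels within each participant (population SD), which removes any
participant-level global scale — so the SD denominator convention (n vs
n−1) cannot affect anything downstream, and a test asserts the scale
invariance directly.

## Confound residualization

Age, sex (one female indicator), scanner (L−1 treatment indicators against
the lexicographically first level; 4 levels by default), and mean FD are
removed from the stacked participant × voxel matrix by per-voxel OLS with
intercept, via a QR projector (`ConfoundRegressor`, a scikit-learn
transformer; idempotent, residuals exactly orthogonal to the design). The
behavior matrix is *not* residualized by default — only the imaging side is
deconfounded — but `Config.deconfound_behavior=True` enables symmetric
removal for sensitivity analyses. Residual means are not added back; the
PLS standardization absorbs location and scale.

## PLS correlation

Both blocks are column z-scored (population SD) pooled over the whole
sample; the cross-product `R = Yzᵀ Xz / (N−1)` is then (up to the factor
N/(N−1)) the behavior-by-voxel correlation matrix. Its SVD `R = U S Vᵀ`
yields min(B, rank) latent components; no further truncation. Sign
ambiguity is resolved by flipping each component so the largest-magnitude
entry of its behavior salience is positive (brain salience and both score
vectors flip jointly). Loadings are Pearson correlations between original
variables and the latent scores; by default the "original" imaging matrix
is the one that actually entered the fit (post-deconfounding), with
`loadings_source="original"` selecting the pre-deconfounding matrix.
Zero-variance columns get NaN loadings and are flagged rather than raised.

## Resampling inference

*Permutation:* behavior rows are shuffled only within each diagnostic
group, so group mean differences cannot generate a component; X is
untouched; the standardization of the permuted Y is recomputed per
replicate. *Bootstrap:* rows are drawn with replacement within each group
(group sizes exactly preserved), jointly from X and Y; each replicate is
refit and its loadings recomputed; the z-score is the original loading
divided by the bootstrap SD (ddof=1) of the replicate loadings, with
|z| ≥ 3 flagged as reliable.

Resampled singular structures are aligned to the original by orthogonal
procrustes on the behavior-side basis: `Q = argmin ‖U_ref − U'Q‖_F`,
aligned saliences `U'Q`, `V'Q`, and aligned null singular values are the
column norms of `diag(S') Q`. A sign-flip-only mode (diagonal ±1 matching)
exists for comparison; rotation is the default. Permutation p-values use
the add-one convention `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, so the
smallest attainable p is exactly `1/(n_perm+1)`. One parent seed spawns one
child seed per replicate (`numpy` SeedSequence), so results are independent
of evaluation order and fully deterministic given the seed.

Empirically (and asserted by the acceptance tests), with a null effect but
strong group offsets planted in both data blocks, the within-group
permutation test rejects LC1 at α = 0.05 at the nominal rate (inside the
exact binomial 95% interval over 200 replicate datasets at 200
permutations, V = 200) — the group restriction is what neutralizes the
offsets.

## Post-hoc battery

Pairwise group contrasts of brain and behavior scores use pooled-variance
two-sample t-tests (Welch behind a flag); continuous severity measures use
Pearson correlations, binary medication flags use t-tests; categorical
composition uses Pearson chi-squared without continuity correction.
Missing values are dropped per test (pairwise deletion) and `n_used` is
reported per row. FDR is Benjamini–Hochberg step-up, applied once per
family: group-score contrasts form one family, severity + medication
associations another. BH is implemented directly (step-up over
`p_(k) ≤ k·q/m`, stable sort for ties) and cross-checked in the tests
against both a brute-force threshold search and statsmodels.

## Synthetic cohort and planted truth

The generator's defaults *are* the emulated study conditions: four groups
(HC 64, BD 63, ADHD 20, BPD 19 — the analyzed sample sizes, which are also
the sums of the published sex and scanner counts), with per-group behavior
moments (ALS/MADRS/YMRS), age, mean FD, sex proportions, and scanner
occupancy fixed at the published values. Moment matching is exact: standard
normal deviates are drawn per group and affinely rescaled so the realized
sample mean and population SD equal the specification to machine precision
(a two-point group {4, 6} realizes mean 5, SD 1). No truncation at zero is
applied by default, since clipping would bias the means away from the
specified values; a `clip_at_zero` mode exists but is off everywhere.

The planted brain–behavior structure is rank one:
`X = scale · latent · bᵀ + group offsets + iid N(0, σ²)`, where `b` is a
unit-norm brain salience supported on 10% of voxels (random signs), the
behavior salience weights ALS and MADRS heavily and YMRS near zero
(0.70/0.70/0.08 before normalization), and `latent` is the standardized
projection of the cohort's behavior matrix onto the true behavior salience.
`scale` is set from the target effect size — the fraction of total X
variance carried by the planted component — via
`scale² = es/(1−es) · V · σ²`. At the default N = 166, V = 2000,
es = 0.5, σ = 1, the first component of the cross-correlation SVD carries
>90% of the covariance and both saliences are recovered with |r| ≥ 0.9.

Synthetic BOLD runs are white Gaussian noise band-passed to 0.01–0.10 Hz
and rescaled per voxel to an exact target SD; motion traces are tiny random
walks (FD ≪ 0.5 mm) plus persistent 0.8 mm translation steps at requested
spike frames, so FD exceeds 0.5 mm at exactly those frames.

**What the generator does not emulate:** spatial autocorrelation,
physiological noise spectra, scanner-specific artifacts beyond additive
offsets, non-Gaussian score distributions, or realistic missingness.
Passing recovery tests therefore demonstrate correctness of the estimator
and inference machinery under the assumed covariance structure, not
robustness to real fMRI noise.

## Problem sizes used in the automated checks

Recovery and minimum-p: 20 seeds at N = 166, V = 2000, effect size 0.5,
with full 1000-permutation nulls on a subset of seeds (the permutation p is
deterministic at its minimum whenever the planted component dominates).
Calibration: 200 replicate datasets × 200 permutations at V = 200.
Bootstrap power/false-flags: 20 seeds at V = 500 with 500 bootstrap
samples. These sizes were chosen so the planted-effect regime matches the
emulated study (N, effect size) while the whole suite completes in about a
minute; the inference defaults in `Config` remain 1000/1000.

## Known limitations

- The clinical severity gates (MADRS > 15, YMRS > 7, strict) are applied to
  whatever cohort enters `run_analysis`; a moment-matched synthetic cohort
  occasionally places a few participants above a gate, so end-to-end runs
  may analyze slightly fewer than the generated N (the flow report accounts
  for every exclusion).
- Procrustes alignment assumes the resampled basis is comparable to the
  original; with near-degenerate singular values the rotation can mix
  components, which is the standard behavior of this alignment family.
- WM/CSF nuisance signals are consumed as given regressor columns; tissue
  extraction, registration, smoothing, and template construction are out of
  scope.
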