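# Methods

This note documents the models, conventions and numerical choices behind
rehokit, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic-data tests do and do not establish
about real data.

## Pipeline overview

For each subject: discard the first `n_discard` volumes (default 10, so a
160-volume TR-3s acquisition contributes n = 150 time points), remove the
least-squares linear trend per voxel, band-pass to 0.01–0.08 Hz, compute
Kendall's W over each in-mask voxel's 27-series neighborhood, divide the
map by its whole-brain-mask mean (mReHo), and smooth with an 8-mm FWHM
Gaussian kernel. At the group level: per-voxel OLS of mReHo on intercept +
patient indicator + mean-centered covariates (age, years of education by
default); the reported statistic is the t of the group coefficient
(positive = patient above control), df = n_subjects − n_columns. Cluster
significance: voxels with |t| above the per-tail p = 0.01 t-quantile are
grouped into connected components (positive and negative tails separately),
and components smaller than a Monte Carlo-calibrated extent `k_min` are
discarded.

## Kendall's W

`W = 12 Σ_i (R_i − R̄)² / (k²(n³ − n))` with `R̄ = k(n+1)/2`. Ties receive
average ranks but W keeps the no-tie denominator; continuous BOLD data make
exact ties a measure-zero event, and any tie-induced excess is clamped to
[0, 1]. In the tie-free case W is an affine function of the mean pairwise
Spearman correlation, `W = ((k−1)ρ̄ + 1)/k`, which the property tests
verify against a brute-force pairwise oracle.

The map computation ranks each voxel's series once (argsort fast path with
a scipy `rankdata` fallback for rows containing ties) and accumulates
neighborhood rank sums with an exact separable 3-point sliding sum for the
full 26-neighbor stencil — exact because rank sums are integers (or exact
halves) far below 2^53, so the vectorized map agrees with a naive
triple-loop implementation to 1e-10 (in practice exactly).

Edge policy: by default (`shrink`) boundary voxels use whatever in-mask
neighbors exist (k = count + 1, minimum 2); `exclude` removes voxels whose
neighborhood is incomplete. Neighborhood stencils of 6, 18 and 26 neighbors
are available; 26 is the default.

Normalization divides by the mask mean of the *unsmoothed* map, so the
normalized map has mask mean exactly 1; smoothing is applied after
normalization. Smoothing is restricted to the mask with kernel
renormalization (smoothed map = smoothed masked values / smoothed mask),
which prevents out-of-brain zeros from deflating edge voxels; σ per axis is
FWHM/(2√(2 ln 2)) converted to voxel units from the affine.

## Temporal filtering

The band-pass is an ideal (hard-edged) mask on the discrete Fourier
transform: bins with frequency in [band_lo, band_hi] are kept verbatim and
all others (DC included) zeroed — the rectangular-band convention of the
classical resting-state toolkits. It is linear, phase-free, idempotent on
in-band content, and rejects stop-band bins exactly (limited only by
spectral leakage). A zero-phase Butterworth (`sosfiltfilt`) alternative is
provided. Detrending precedes filtering. An upper band edge at or above the
Nyquist frequency 1/(2·TR) is an error.

## Monte Carlo cluster-extent calibration

Each iteration draws white Gaussian noise on the full grid, smooths it to
the nominal FWHM, standardizes by the in-mask sample mean/SD (so the voxel
threshold is exact regardless of the variance change induced by smoothing),
thresholds both tails, and records the largest connected component over
both tails. `k_min(α)` is the smallest extent whose exceedance frequency in
the null distribution of maxima is ≤ α.

Tail convention. `voxel_p` is interpreted as the suprathreshold probability
*per tail* (threshold at the one-sided Gaussian quantile), which is what the
classical AlphaSim implementations do with their "individual voxel P"
input; under the study parameters (3-mm ~54k-voxel whole-brain-scale mask,
FWHM 8 mm, p = 0.01, 1000 iterations, α = 0.05) this yields a minimum
cluster volume near 2.1–2.3 cm³, consistent with the ~2 cm³ thresholds such
pipelines report. The alternative reading — splitting p symmetrically
across both tails — is available as `tail_convention="split"` and yields
systematically smaller thresholds (~1.5 cm³ under the same parameters)
because each tail then carries only p/2. The same per-tail quantile is used
to threshold the real t-map, keeping simulation and analysis consistent.

Connectivity defaults to 18 (face + edge neighbors), matching the ~5-mm
clustering radius convention of the AlphaSim lineage at 3-mm voxels; 6 and
26 are selectable. Labels are deterministic: ordered by descending extent,
ties broken by first voxel index in array order. The cluster report lists
extent (voxels and mm³ via the affine determinant), the signed peak t and
its world coordinate `affine·(i,j,k,1)`, and per-group mean mReHo over the
cluster.

The null noise is smoothed with the NOMINAL FWHM — the value fed to the
procedure, normally the applied smoothing kernel — not with a smoothness
estimated from the data; estimated-smoothness modes are out of scope. See
Limitations for the consequence.

## Group and demographic statistics

The voxelwise model is mass-univariate OLS, fit independently per voxel
with a shared pinv-free normal-equations solve; rank-deficient designs are
rejected with the collinear columns named. Voxels whose residuals are
indistinguishable from rounding noise (RSS ≤ 1e4·eps·‖y‖²) are flagged
degenerate and given a 0 or ±inf sentinel instead of a meaningless finite
t. One-sample maps test mean = 1 (the mReHo baseline) by default, with FDR
control via Benjamini–Hochberg.

Demographics mirror the univariate tests of a clinical table: a two-sample
t from summary statistics `t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b)` —
identical to the pooled-variance t at equal n — with degrees of freedom
reported under both the pooled and Welch conventions (published tables
rarely state which was used); Pearson chi-square without continuity
correction for the 2×2 sex table; Mann–Whitney U and Pearson correlation
(e.g. ReHo vs months on dialysis) as companions. The cigarettes/day
comparison uses smokers only, which is the only way such printed values are
recoverable when most of a cohort does not smoke.

## Synthetic cohorts

`generate_subject_scan` produces, on a common grid with the world origin at
the mask centroid: (a) spatially smooth Gaussian noise — white noise
Gaussian-filtered volume by volume, rescaled by the exact kernel L2 norm so
the per-voxel SD equals `noise_sd` — independent across volumes; (b) an
independent white-noise floor (`white_noise_sd`) that keeps W strictly
below 1; and (c) per spherical ROI one shared time course, built by
assigning random complex coefficients to the 0.01–0.08 Hz Fourier bins
(unit RMS, exactly band-limited), scaled by the group's amplitude. A shared
in-band time course is precisely what ReHo detects, so the implanted
amplitude is a monotone dial on the group difference.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| grid_shape | 32×38×32 (desk) / 61×73×61 preset | fast tests; full 3-mm MNI-scale grid available |
| voxel_size_mm | 3 | the resampled analysis resolution |
| n_volumes, tr_s | 160, 3.0 s | the targeted acquisition length |
| noise_sd / white_noise_sd | 1.0 / 0.5 | smooth-to-white mix; keeps baseline W ≈ 0.3 |
| spatial_noise_fwhm_mm | 6 | typical effective smoothness of 3-mm EPI data |
| roi radius | 9 mm | ~115 voxels, the scale of reported clusters |
| group_effect | patient 1.6, control 0 | gives ≈ 0.55 within-ROI mReHo group difference, well above the 0.1 design floor |
| n_per_group | 20 | typical clinical cohort size (15:5 male:female per group) |

Metadata emulates a hemodialysis case-control table: ages in the late 30s,
~12 years of education, near-ceiling MMSE, ~1 year on dialysis; the exact
counts (15:5 sex ratio per 20 subjects, 2 vs 3 smokers, 3 outpatients with
unknown dialysis duration) are deterministic. Subject seeds derive
deterministically from the master seed; identical config + seed is
bit-identical.

What the generator does **not** model: temporal autocorrelation of BOLD
noise (no downstream stage assumes it), physiological cardiac/respiratory
structure, head motion, EPI distortion, anatomical contrast, or
between-subject anatomical variability. Passing tests therefore establish
the pipeline's correctness and calibration under idealized aligned
Gaussian-noise conditions, not robustness to real-scanner artifacts.

## Numerical choices

- Ranks: average-rank ties; rank path is exact (argsort + tie fallback).
- W clamped to [0, 1]; k < 2 neighborhoods are excluded from the map mask.
- Null fields standardized per iteration by in-mask sample moments.
- `k_min` search is an exhaustive scan from 1; α below 1/n_iterations is
  rejected with a suggestion to raise the iteration count.
- TR source of truth: an explicit configuration value overrides the NIfTI
  header `pixdim[4]`; a zero/absent header TR without an override is an
  error.
- All tabular outputs are TSV with header rows; missing values are empty
  fields. The pipeline writes a manifest (config snapshot, content hashes,
  stage timings); deterministic stages reproduce identical hashes.

## Problem sizes used by the test suite

Unit and property tests run on 5³–16³ grids with 20–60 volumes. The
calibration suites use the desk-scale preset (32×38×32, ~15k-voxel mask,
160 volumes, 12 subjects per group, 10 cohorts) and a 1000-iteration null
for the extent threshold; the whole-brain Monte Carlo check runs 1000
iterations on the ~54k-voxel full-size mask. The complete suite finishes in
under ten minutes on one CPU.

## Limitations

- **Nominal-FWHM cluster correction is anticonservative on ReHo maps.**
  Smoothed mReHo maps are smoother than the applied 8-mm kernel: Kendall
  neighborhoods share 18–26 of 27 series between adjacent voxels, and the
  scan noise itself is spatially smooth, so the effective map FWHM exceeds
  the nominal value handed to the Monte Carlo null. Calibrating `k_min`
  with the nominal FWHM — the convention this package reproduces —
  therefore under-corrects: in the zero-effect calibration suite one cohort
  in ten shows a false-positive surviving cluster at α = 0.05, which the
  corresponding test reports as a failure rather than hiding. Users who
  need exact family-wise control should enlarge the FWHM passed to
  `McParams` toward the measured smoothness of their maps; automatic
  smoothness estimation from residual fields is deliberately out of scope.
- The t-map null simulation uses Gaussian fields; at small group sizes the
  heavier t tails make cluster sizes at a matched threshold slightly
  larger, a second-order contribution to the same anticonservatism.
- The equal-variance demographic t matches published tables at equal n;
  for unequal n the Welch df is reported alongside but the statistic keeps
  the unpooled-SE form.
- The ellipsoidal brain mask reproduces the voxel count and compactness of
  a whole-brain mask, not its morphology; `k_min` depends mildly on mask
  shape (a few percent).
- Which ReHo summary (cluster mean vs peak) enters duration-of-illness
  correlations is a reporting choice; the cluster mean is used here.
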