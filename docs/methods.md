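# Methods

`lcpipe` implements a desk-scale analysis chain for a two-condition
(novelty / repetition) block-design BOLD experiment: hemodynamic response
function (HRF) estimation by orthonormal basis expansion, activation and
seed-connectivity GLMs built on the estimated HRFs, and voxel-wise
longitudinal mixed-effects mapping with cluster-extent and false-discovery
corrections. Because the motivating data (an aging cohort with locus
coeruleus task fMRI, amyloid PET and longitudinal cognition) are access
restricted, the package ships a first-class synthetic-data generator; every
quantitative claim the package makes is established on synthetic ground
truth by the studies in `lcpipe.studies`.

## Signal model and HRF estimation

The BOLD series of a run is modelled as the sum of two parallel
finite-impulse-response systems, one per condition:

    y(n) = Σ_m h1(n−m) x1(m) + Σ_m h2(n−m) x2(m) + e(n)

with `x1`, `x2` the block indicator series on the TR grid and `h1`, `h2`
condition-specific HRFs of finite memory `M` (24 s by default). Each HRF is
expanded in `L` orthonormal basis functions, `h_i = Σ_j c_ij b_ij`, turning
deconvolution into OLS on the regressors `v_ij = x_i ∗ b_ij`.

The basis is built from spherical Laguerre functions

    d_j(t) = sqrt(j!/(j+2)!) · exp(−t/(2α)) / α^{3/2} · K_j(t/α),

where `K_j` is the generalized Laguerre polynomial of order 2 and `α > 0`
sets the decay scale. Each `d_j` is convolved with a discrete Gaussian of SD
`σ = 1 s` centred at a pure delay `τ ≥ 0` (truncated at ±4σ and renormalized
to unit sum), then the columns are Gram–Schmidt orthonormalized in index
order (realized as thin QR with positive diagonal). The printed form of the
spherical Laguerre function sometimes carries a growing exponent `e^{t/2α}`;
the functions are only a usable basis for causal finite-memory systems with
the decaying sign, which is what this package implements. `α`, `τ`, `σ` are
in seconds; curves are sampled at `dt = TR` by default.

Hyper-parameters are chosen per subject in two steps, as in practice:
`(α, τ)` minimize a leave-one-run-out cross-validated mean squared
prediction error averaged over a small set of ROI-mean series (grids
`α ∈ {0.25, …, 3.0}` s, `τ ∈ {0, 0.5, …, 4.0}` s; exact ties break toward
smaller `τ`, then smaller `α`), and the shared order `L` minimizes
`BIC = N ln(RSS/N) + p ln N` (selected `L = 2` on data generated at order
2). Voxel-wise coefficients are then fitted with the selected subject basis.
Multi-run fits demean each run (response and regressors) and share the
coefficients, which absorbs per-run offsets without intercept columns; CV
prediction operates on the demeaned held-out run.

A caveat the studies quantify: neighbouring `(α, τ)` grid points produce
bases spanning nearly the same L-dimensional space (relative span gap
~4·10⁻⁶ at the default grids), so the *labels* `(α, τ)` are only
identifiable at high SNR (recovery ≈100% when noise is 3% of signal, ~40%
at unit SNR), while the estimated *curves* — the scientifically relevant
output — correlate ≥0.99 with truth at unit voxel SNR thanks to ROI
averaging in the first step. HRF summaries report the signed
largest-magnitude extremum (amplitude), its time (peak latency) and the
width of that lobe at half magnitude with linear interpolation (FWHM).
Group HRF shape is the first principal component of the uncentred curve
stack (uncentred so that identical curves yield their own shape at 100%
explained variance), sign-fixed positive at its largest extremum.

## Activation and gPPI GLMs

Activation contrasts re-fit the data with the estimated HRFs rather than
reading amplitudes off the curves: regressors `x_i ∗ ĥ_i` are z-transformed
per run, entered into an OLS GLM with intercept, and the
novelty-versus-repetition (NvR) contrast is the PE difference, averaged
across runs per subject.

gPPI uses five regressors: the demeaned seed-ROI mean series
(physiological), the two block series convolved with the group-level seed
HRF (psychological), and their elementwise products (interactions). The
connectivity contrast is the difference of the two interaction PEs.
Products are taken at the BOLD level — no deconvolution of the seed to a
neural-level series, unlike some gPPI variants. The physiological regressor
is demeaned before multiplication so the interactions do not alias the
psychological main effects. Psychological regressors are not z-transformed
(standardization belongs to the activation GLM only; a switch exists).
Coupling recovery in absolute units requires a scale convention: the
synthetic generator gates the seed series with a unit-peak HRF, so studies
supply a unit-peak group HRF to the gPPI design.

## Preprocessing (desk scale)

The emulated preprocessing chain is scrub → nuisance regression →
smoothing. Confounds are the 30-column expansion: 3 nuisance-ROI means
(4th ventricle, lateral ventricles, white matter), 6 motion parameters,
their backward-difference derivatives (leading 0), and the squares of all
15. DVARS is the RMS across in-mask voxels of the temporal backward
difference; the default scrub rule removes volumes above the 75th
percentile + 1.5 IQR of the run's DVARS (an absolute threshold is
accepted), and removal propagates to the GLM design rows via sample masks.
Ellipsoid smoothing is a separable axis-aligned anisotropic Gaussian with
per-axis FWHM in mm and unit-mass kernel (constants preserved); arbitrary
kernel orientation belongs to registration, which is out of scope. A
seed-versus-4th-ventricle Pearson correlation serves as a partial-volume
diagnostic. Brain extraction, slice timing, realignment, ICA denoising and
registration are not implemented; their net effect is emulated by the
generator's confound structure.

## Longitudinal mixed model

The outcome (a PACC5-like cognitive composite) for subject *i* at visit *j*
is modelled as

    y_ij = β0 + β1 Age_i + β2 Sex_i + β3 Edu_i + β4 PredA_i + β5 PredB_i
         + (β6 Age_i + β7 Sex_i + β8 Edu_i + β9 PredA_i + β10 PredB_i
            + β11 PredA_i·PredB_i)·Time_ij + b_0i + b_si·Time_ij + e_ij

with `PredA` an imaging contrast, `PredB` amyloid burden (PiB DVR,
continuous or dichotomized at the 1.324 cut-off), time in years since
baseline, Gaussian random intercepts and slopes per subject, ML estimation
(statsmodels MixedLM) and Wald Z inference on fixed effects. A fixed
time main effect is included alongside the covariate-by-time terms.
Model (i) omits the amyloid moderation; model (ii) is the full three-way
form. Covariate-by-time terms with p > 0.10 are dropped and the model
refitted, provided the remaining estimates change by < 10% (the pruning
rule); when the slope variance collapses to the boundary or the fit fails,
the model falls back to a random intercept only. Wald Z (normal reference)
is mildly anticonservative at 150 subjects (measured type-I ≈ 0.057 at
nominal 0.05 over 1000 null replicates); a Kenward–Roger-style correction
is not available in the backend and ML is retained deliberately.

Simple slopes evaluate the time-slope and its SE at moderator levels
(mean ± 1 SD by default) through linear combinations of the fixed effects
and their covariance; other time-interacting variables are held at 0 unless
specified. The floodlight analysis Wald-tests the conditional
predictor-by-time effect `β9 + β11·b` over a grid of amyloid values `b`,
applies BH-FDR across grid points, and reports the significant region; the
closed-form Johnson–Neyman boundary (roots of a quadratic in `b`) is the
analytic cross-check.

Voxel-wise mapping fits the model per voxel (`fit_voxelwise_lme`), flagging
non-converging voxels as missing. Cluster-extent inference on interaction
maps uses a plug-in GLS approximation: variance components estimated once
from the voxel-averaged predictor model, subject blocks whitened with the
implied marginal covariance, per-voxel Wald Z from whitened OLS (deviating
from the full ML Z by < 0.35 in absolute value, r > 0.99, in the
cross-check test). The max-cluster-size null uses Freedman–Lane
permutation — reduced-model residuals re-assigned across subjects with the
reduced fit added back — because naively permuting the subject-to-map
assignment is badly conservative when a strong true effect inflates the
outcome variance. One-sample group maps (activation, connectivity) instead
use exact sign-flip permutation of subject maps. Clusters form at
`|Z| > cdt` (presets 4.5 / 3.1 / 2.3) with 26-connectivity, and cluster
FWER p is `(1 + #{null max ≥ size}) / (n_perm + 1)`.

PACC5 averages five baseline-referenced z-scores (DSST, FCSRT free+total,
Logical Memory delayed, MMSE, category fluency); at most one missing
subtest is allowed, missing subtests are excluded from the average. The
memory and executive composites use the same rule with their subtests;
Trails B−A is sign-flipped so all composites increase with better
performance. Reliability is the two-way mixed-effects consistency ICC,
single measure (ICC(3,1)), computed from ANOVA mean squares on subjects
with complete visit schedules (single-visit subjects excluded and logged);
the variant is a package choice, cross-checked against pingouin's ICC(C,1).

## Synthetic data

The generator reproduces the encoding paradigm: per run, a 5-s fixation,
then novelty / repetition / novelty / repetition blocks of 40 s (7 trials
of 4.75 s padded by jittered fixation; the jitter distribution is uniform
padding summing to the block budget, configurable), separated by 25-s
fixations, closing with a 5-s fixation — 245 s scheduled. With TR = 2 s and
the default 127 volumes, trailing fixation absorbs the 9-s difference so
both printed figures (4 min 5 s schedule; 127 volumes) hold. Onsets snap to
the nearest TR sample; no slice-timing model.

BOLD runs place the two-condition convolution signal in labelled ROI masks
on a small grid (12×12×8 default), add condition-gated copies of the noisy
seed-mean series to the target mask (gPPI ground truth), and superimpose
AR(1) noise (stationary initialization), linear drift and random-phase
sinusoids, alongside six random-walk motion series and the three
nuisance-ROI means. Defaults: innovation SD 0.5, AR(1) 0.3, drift
0.002 s⁻¹, one 0.03-Hz sinusoid of amplitude 0.1.

Cohorts draw age ~ N(70.1, 8.9²), sex ~ Bernoulli(0.55) (0/1 code),
education ~ uniform integers 12–20, an N(0,1) imaging predictor, and
amyloid DVR from a two-component mixture (negative ~1.18 ± 0.05, positive
~1.84 ± 0.45, truncated at the 1.324 cut-off so mixture membership and
dichotomous classification coincide; positive weight 36/128 with
stratified membership so the default cohort composition is exact).
Outcomes follow the mixed model above; default variance components
(intercept SD 0.8, slope SD 0.08 /yr, residual SD 0.35) sit at the scale
of a z-scored cognitive composite in a preclinical cohort. Five annual
visits per subject by default; explicit per-subject schedules (dropout)
are accepted, with a baseline visit required.

What the generator does not emulate — scanner reconstruction, slice
timing, susceptibility artifacts, realistic head motion, registration
error, non-Gaussian cognitive floors/ceilings — bounds what passing tests
show: they validate the estimators and their calibration under the stated
model, not robustness to those artifacts.

## Study and test dimensioning

The validation studies run at: HRF recovery 50 seeds × 6 runs (curve
clause at unit voxel SNR, grid-identification clause at 3% noise); order
selection 50 replicates at SNR 10; gPPI 100 replicates × 3 runs (couplings
0.8/0.2 and the 0.5/0.5 null, AR(1)+sinusoid noise without drift — the
5-regressor model carries no drift column, and drift removal is the
preprocessing stage's job); mixed-model calibration 2000 null cohorts
and recovery 200 cohorts at 150 subjects × 5 visits; cluster FWER
calibration 1000 outer replicates of 20 smooth null maps on a 12×12×8 grid
with 128 sign-flips each; the planted-blob end-to-end check 25 replicates
on an 8×8×4 grid with 150 Freedman–Lane permutations. The acceptance
script (`scripts/acceptance.py`) reruns the same studies at reduced
replicate counts sized for a few minutes of runtime; all quantities are
computed fresh from the given seed.

## Known limitations

- Wald Z on ML fits is mildly anticonservative at cohort scale (see above).
- `(α, τ)` are weakly identified near the optimum; treat them as nuisance
  smoothing parameters, not estimands.
- The GLS cluster route plugs in one set of variance components for all
  voxels; voxels with strongly heterogeneous random-effect structure would
  deviate more than the measured cross-check bound.
- The ellipsoid kernel is axis-aligned; oriented structures not aligned
  with the grid axes receive no special treatment.
- Freedman–Lane block permutation requires identical visit schedules
  across subjects; unbalanced cohorts need the slower per-voxel ML route.
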