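# lcpipe

Task-fMRI analysis chain for two-condition (novelty / repetition) block
designs: hemodynamic response function (HRF) estimation by spherical
Laguerre basis expansion, activation and seed-connectivity (gPPI) GLMs
built on the estimated HRFs, and voxel-wise longitudinal mixed-effects
mapping of imaging–cognition associations with cluster-extent FWER,
BH-FDR and floodlight (Johnson–Neyman) analyses.

The package targets the kind of study where a small brainstem seed (the
locus coeruleus) is examined for novelty-related activity and
connectivity, and those imaging measures are related to longitudinal
cognitive decline moderated by amyloid burden (PiB DVR). Because such
cohort data are access restricted, `lcpipe` ships a first-class synthetic
data generator that emulates the paradigm (six 245-s runs of 40-s
novelty/repetition blocks with 7 face-name trials each, TR 2 s, 127
volumes), region-specific HRFs, realistic noise and confounds, an amyloid
DVR mixture with the 1.324 positivity cut-off, and longitudinal cohorts
with planted interaction effects — so every stage is testable against
known ground truth.

## The models

**BOLD signal.** Each run is the sum of two parallel FIR systems,
`y(n) = Σ_m h1(n−m)x1(m) + Σ_m h2(n−m)x2(m) + e(n)`, with condition block
series `x_i` and finite-memory HRFs `h_i`. Each HRF is expanded in `L`
orthonormal basis functions built from spherical Laguerre functions
`d_j(t) = sqrt(j!/(j+2)!) · e^{−t/2α}/α^{3/2} · K_j(t/α)` (with `K_j` the
generalized Laguerre polynomial of order 2), convolved with a Gaussian
delay kernel `g(τ, σ=1 s)` and Gram–Schmidt orthonormalized. `(α, τ)` are
selected per subject by grid search on a leave-one-run-out cross-validated
generalization error; `L` by BIC. Expansion coefficients come from OLS.

**Connectivity.** gPPI with five regressors — the demeaned seed mean
series, two psychological regressors (block series ∗ group-level seed
HRF), and their products — whose interaction-PE difference is the
novelty-versus-repetition (NvR) connectivity contrast.

**Longitudinal model.** For outcome `y_ij` (a PACC5-like composite) of
subject *i* at visit *j* (time in years):

    y_ij = β0 + β1 Age + β2 Sex + β3 Edu + β4 PredA + β5 PredB
         + (β6 Age + β7 Sex + β8 Edu + β9 PredA + β10 PredB
            + β11 PredA·PredB)·Time_ij + b_0i + b_si·Time_ij + e_ij

fitted by ML with random intercepts and time-slopes, Wald Z inference,
covariate-by-time pruning at p > 0.10, cluster-extent FWER by permutation
(sign flips for one-sample maps, Freedman–Lane for interaction maps), and
floodlight analysis of the amyloid range where the imaging–decline
association is significant.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from lcpipe import (make_task_design, GroundTruth, NoiseSpec, simulate_bold_run,
                    HrfBasisModel, simulate_cohort,
                    LongitudinalInteractionModel, LmeSpec)
from lcpipe.simulate import make_ground_truth_hrf

designs = make_task_design()                      # 6 runs, 127 volumes, TR 2 s
h = make_ground_truth_hrf("double-gamma", dt=2.0)
gt = GroundTruth(hrf_nov=h, hrf_rep=0.6 * h, noise=NoiseSpec(white_sd=0.4))
runs, masks = [], None
for d in designs:
    data, conf, masks = simulate_bold_run(d, gt, seed=d.run_index)
    runs.append(data)
y = [r[masks["active"]].mean(axis=0) for r in runs]

model = HrfBasisModel.from_grid_search(y, designs)  # two-step estimation
print(model.fit().summary())

cohort = simulate_cohort(128, {"b9": -0.1, "b11": 0.2}, seed=1)
lme = LongitudinalInteractionModel.from_dataframe(cohort, LmeSpec(model="ii")).fit()
fl = lme.floodlight()
print(f"three-way estimate: {lme.params['pred:_pib:time_years']:.3f} "
      f"(z = {lme.zvalues['pred:_pib:time_years']:.2f})")
print(f"floodlight: significant for DVR >= {fl.region_min:.2f}")
```

prints

```
HRF basis-expansion fit
  runs: 6   alpha=3  tau=4  L=2
  in-sample mse: 0.028917   BIC: -2673.5
  novelty      amplitude=+1.1894  peak=4.00 s  fwhm=4.30 s
  repetition   amplitude=+0.3641  peak=4.00 s  fwhm=4.51 s
three-way estimate: 0.164 (z = 4.42)
floodlight: significant for DVR >= 1.05
```

The estimated novelty amplitude exceeds the repetition amplitude by about
the planted 1 : 0.6 ratio (scaled by the condition regressor norms), the
HRF peaks at the sample nearest the true 5-s latency, the planted
three-way interaction β11 = 0.2 is recovered (0.164 ± z = 4.4), and the
floodlight lower bound sits at the bottom of the observed DVR range
because the planted effect is significant throughout it.

A CLI mirrors the stages (`lcpipe simulate | prep | fit-hrf | activation |
gppi | group-lme | run-all | report`); `lcpipe run-all -o out --seed 1`
writes NIfTI maps, TSV/CSV tables and a JSON report into `out/`.

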