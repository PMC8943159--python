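"""Synthetic task designs, BOLD runs and cohorts."""

import numpy as np
import pandas as pd
import pytest

from lcpipe.basis import build_basis
from lcpipe.simulate import (AmyloidMixture, BlockSpec, GroundTruth,
                             NoiseSpec, PIB_CUTOFF, default_roi_masks,
                             make_ground_truth_hrf, make_task_design,
                             simulate_bold_run, simulate_cohort)


class TestTaskDesign:
    def test_scheduled_duration_is_245s(self, designs):
        assert BlockSpec().scheduled_duration_s == pytest.approx(245.0)

    def test_default_run_count_and_grid(self, designs):
        assert len(designs) == 6
        d = designs[0]
        assert d.n_volumes == 127 and d.tr_seconds == 2.0
        assert len(d.x1) == len(d.x2) == 127

    def test_seven_trials_per_novelty_block(self, designs):
        nov = [e for e in designs[0].events if e[0] == "novelty"]
        assert len(nov) == 14  # 7 trials x 2 blocks per run
        blocks = designs[0].block_intervals("novelty")
        assert len(blocks) == 2

    def test_conditions_never_overlap(self, designs):
        for d in designs:
            assert not np.any((d.x1 > 0) & (d.x2 > 0))

    def test_events_fit_in_run(self, designs):
        for d in designs:
            for _, onset, dur in d.events:
                assert onset >= 0
                assert onset + dur <= d.n_volumes * d.tr_seconds + 1e-9

    def test_zero_task_blocks(self):
        spec = BlockSpec(block_order=())
        d = make_task_design(2.0, 1, spec, n_volumes=10)[0]
        assert np.all(d.x1 == 0) and np.all(d.x2 == 0)
        assert len(d.x1) == 10

    def test_overflow_names_amount(self):
        with pytest.raises(ValueError, match="45"):
            make_task_design(2.0, 1, n_volumes=100)  # 200 s < 245 s

    def test_jitter_preserves_block_budget(self):
        d_eq = make_task_design(n_runs=1)[0]
        d_jit = make_task_design(n_runs=1, seed=7)[0]
        # jitter moves trial onsets but x marks the same block samples
        assert np.array_equal(d_eq.x1, d_jit.x1)
        assert d_eq.events != d_jit.events

    def test_determinism(self):
        a = make_task_design(seed=3)
        b = make_task_design(seed=3)
        assert a[0].events == b[0].events


class TestGroundTruthHrf:
    def test_double_gamma_peaks_near_5s(self):
        dt = 0.1
        h = make_ground_truth_hrf("double-gamma", dt=dt)
        # dense-grid argmax oracle of the closed-form gamma difference
        from scipy import stats
        tt = np.linspace(0, 24, 24001)
        dense = stats.gamma.pdf(tt, 6) - stats.gamma.pdf(tt, 16) / 6
        t_peak = tt[np.argmax(dense)]
        assert abs(np.argmax(h) * dt - t_peak) <= dt
        assert h[0] == 0.0

    def test_laguerre_composed_is_exact_reconstruction(self, basis_default):
        coef = np.array([0.3, 0.7])
        h = make_ground_truth_hrf("laguerre",
                                  {"basis": basis_default, "coef": coef})
        assert np.array_equal(h, basis_default.B @ coef)

    def test_amplitude_scaling_is_pointwise(self):
        h1 = make_ground_truth_hrf("double-gamma", {"amplitude": 1.0})
        h2 = make_ground_truth_hrf("double-gamma", {"amplitude": 2.0})
        assert np.allclose(h2, 2 * h1)

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth_hrf("gamma-delay", {"scale": -1.0})
        with pytest.raises(ValueError):
            make_ground_truth_hrf("double-gamma", {"peak1": 0.0})


class TestSimulateBold:
    def test_noiseless_run_is_exact_convolution(self, designs, quiet_noise,
                                                span_truth):
        h, _ = span_truth
        gt = GroundTruth(hrf_nov=h, hrf_rep=h, beta_nov=2.0, beta_rep=0.5,
                         noise=quiet_noise)
        d = designs[0]
        data, conf, masks = simulate_bold_run(d, gt, seed=0)
        expect = (2.0 * np.convolve(d.x1, h)[:d.n_volumes]
                  + 0.5 * np.convolve(d.x2, h)[:d.n_volumes])
        voxel = data[masks["active"]][0]
        assert np.allclose(voxel, expect, atol=1e-12)
        outside = data[~(masks["active"] | masks["seed"])]
        assert np.allclose(outside, 0.0)

    def test_fixed_seed_bit_identical(self, designs, span_truth):
        h, _ = span_truth
        gt = GroundTruth(hrf_nov=h, hrf_rep=h)
        a, ca, _ = simulate_bold_run(designs[0], gt, seed=11)
        b, cb, _ = simulate_bold_run(designs[0], gt, seed=11)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_white_noise_sd_recovered(self, designs, span_truth):
        # Monte-Carlo: residual SD after subtracting the known signal
        h, _ = span_truth
        sd = 0.7
        gt = GroundTruth(hrf_nov=h, hrf_rep=h, beta_nov=1.0, beta_rep=0.5,
                         noise=NoiseSpec(white_sd=sd, ar1=0.0,
                                         drift_slope=0.0, physio_amps=(0.0,)))
        d = designs[0]
        signal = (np.convolve(d.x1, h)[:d.n_volumes]
                  + 0.5 * np.convolve(d.x2, h)[:d.n_volumes])
        resid = []
        for s in range(500):
            data, _, masks = simulate_bold_run(d, gt, grid_shape=(10, 10, 7),
                                               seed=s)
            resid.append(data[masks["active"]][0] - signal)
        emp = np.std(np.concatenate(resid))
        assert emp == pytest.approx(sd, rel=0.03)

    def test_invalid_noise_parameters(self):
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=-0.1)
        with pytest.raises(ValueError):
            NoiseSpec(ar1=1.0)

    def test_roi_masks_disjoint(self, masks):
        total = np.zeros(next(iter(masks.values())).shape, dtype=int)
        for m in masks.values():
            total += m
        assert total.max() == 1


class TestSimulateCohort:
    def test_null_model_all_zero(self):
        coh = simulate_cohort(20, random_effect_sds=(0, 0, 0, 0), seed=0)
        assert np.allclose(coh["outcome"], 0.0)

    def test_pred_main_effect_identity(self):
        coh = simulate_cohort(20, {"b4": 1.0},
                              random_effect_sds=(0, 0, 0, 0), seed=1)
        assert np.allclose(coh["outcome"], coh["pred"])

    def test_every_subject_has_baseline(self):
        coh = simulate_cohort(30, seed=2)
        base = coh.groupby("subject")["time_years"].min()
        assert np.allclose(base, 0.0)

    def test_amyloid_share_is_stratified_exactly(self):
        coh = simulate_cohort(128, seed=5)
        share = coh.groupby("subject")["amyloid_positive"].first().mean()
        assert share == pytest.approx(36 / 128, abs=1e-12)

    def test_positive_fraction_matches_mixture_mass(self):
        # with Bernoulli membership the classified-positive fraction
        # converges to the mixture weight (components truncated at cut-off)
        mix = AmyloidMixture(weight_positive=0.3)
        coh = simulate_cohort(4000, amyloid_mixture=mix,
                              stratify_amyloid=False, seed=6,
                              visit_schedule=[np.array([0.0])] * 4000)
        frac = coh.groupby("subject")["amyloid_positive"].first().mean()
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 4000))

    def test_dvr_positive_and_consistent_with_cutoff(self):
        coh = simulate_cohort(60, seed=7)
        assert (coh["pib_dvr"] > 0).all()
        assert ((coh["pib_dvr"] > PIB_CUTOFF) == coh["amyloid_positive"]).all()

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(10, random_effect_sds=(-1, 0, 0, 1))

    def test_determinism(self):
        a = simulate_cohort(25, seed=9)
        b = simulate_cohort(25, seed=9)
        pd.testing.assert_frame_equal(a, b)
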