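"""HRF estimation: expansion design, OLS fit, CV, selection, summaries."""

import numpy as np
import pytest

from lcpipe.basis import build_basis
from lcpipe.hrf import (HrfBasisModel, build_expansion_design,
                        cv_generalization_error, fit_bold_model,
                        grid_search_basis, group_hrf_shape, hrf_summaries,
                        reconstruct_hrf, select_model_order)
from lcpipe.simulate import GroundTruth, NoiseSpec, TaskDesign, \
    make_task_design, simulate_bold_run

from conftest import noiseless_runs


def impulse_design(n=40, at=0):
    x1 = np.zeros(n)
    x1[at] = 1.0
    return TaskDesign(tr_seconds=2.0, n_volumes=n, x1=x1, x2=np.zeros(n),
                      events=())


class TestExpansionDesign:
    def test_impulse_reproduces_basis_columns(self, basis_default):
        d = impulse_design()
        V, slices = build_expansion_design(d, basis_default, basis_default)
        for j in range(basis_default.L):
            expect = np.zeros(40)
            expect[:13] = basis_default.B[:, j]
            assert np.allclose(V[:, j], expect, atol=1e-14)

    def test_empty_condition_gives_zero_columns(self, basis_default):
        d = impulse_design()
        V, slices = build_expansion_design(d, basis_default, basis_default)
        assert np.allclose(V[:, slices["repetition"]], 0.0)

    def test_boxcar_matches_bruteforce_convolution(self, basis_default):
        n = 60
        x1 = np.zeros(n)
        x1[5:15] = 1.0
        d = TaskDesign(tr_seconds=2.0, n_volumes=n, x1=x1, x2=np.zeros(n),
                       events=())
        V, _ = build_expansion_design(d, basis_default, basis_default,
                                      intercept=False)
        # direct O(N*M) convolution oracle
        for j in range(basis_default.L):
            b = basis_default.B[:, j]
            expect = np.array([sum(b[m] * x1[t - m]
                                   for m in range(min(t + 1, len(b))))
                               for t in range(n)])
            assert np.max(np.abs(V[:, j] - expect)) <= 1e-10

    def test_mismatched_dt_rejected(self, basis_default):
        d = impulse_design()
        bad = build_basis(2, 12, 1.0, dt=1.0)
        with pytest.raises(ValueError, match="dt"):
            build_expansion_design(d, bad, bad)


class TestFitBoldModel:
    def test_noiseless_recovery(self, basis_default):
        x1 = np.zeros(60)
        x1[0] = 1.0
        x2 = np.zeros(60)
        x2[25] = 1.0
        d = TaskDesign(tr_seconds=2.0, n_volumes=60, x1=x1, x2=x2, events=())
        V, slices = build_expansion_design(d, basis_default, basis_default)
        c0 = np.zeros(V.shape[1])
        c0[:2] = [0.8, -0.3]
        c0[-1] = 1.5
        fit = fit_bold_model(V @ c0, V, slices)
        assert np.allclose(fit.c, c0, atol=1e-10)
        assert np.max(np.abs(fit.V.T @ fit.residuals)) <= 1e-8

    def test_orthonormal_design_projection(self):
        rng = np.random.default_rng(0)
        V, _ = np.linalg.qr(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        fit = fit_bold_model(y, V)
        assert np.allclose(fit.c, V.T @ y, atol=1e-12)

    def test_coefficient_covariance_matches_theory(self):
        # Monte-Carlo vs sigma^2 (V'V)^-1
        rng = np.random.default_rng(1)
        V = rng.normal(size=(80, 3))
        c0 = np.array([1.0, -0.5, 0.2])
        sigma = 0.4
        est = np.array([fit_bold_model(V @ c0 + rng.normal(0, sigma, 80), V).c
                        for _ in range(1000)])
        emp = np.cov(est.T)
        theory = sigma**2 * np.linalg.inv(V.T @ V)
        scale = np.sqrt(np.outer(np.diag(theory), np.diag(theory)))
        assert np.max(np.abs(emp - theory) / scale) < 0.1

    def test_rank_deficiency_names_columns(self):
        V = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="collinear"):
            fit_bold_model(np.zeros(20), V)


class TestReconstruct:
    def test_unit_vector_gives_basis_column(self, basis_default):
        d = impulse_design()
        V, slices = build_expansion_design(d, basis_default, basis_default)
        c = np.zeros(V.shape[1])
        c[0] = 1.0
        from lcpipe.hrf import ExpansionFit
        fit = ExpansionFit(c=c, residuals=np.zeros(40), mse=0.0, bic=0.0,
                           V=V, slices=slices)
        est = reconstruct_hrf(fit, basis_default, "novelty")
        assert np.allclose(est.h, basis_default.B[:, 0])
        zero = reconstruct_hrf(fit, basis_default, "repetition")
        assert zero.amplitude == 0.0 and np.allclose(zero.h, 0.0)
        with pytest.raises(KeyError):
            reconstruct_hrf(fit, basis_default, "oddball")

    def test_in_span_truth_recovered_exactly(self, designs, basis_default,
                                             span_truth):
        h_true, _ = span_truth
        runs, masks = noiseless_runs(designs, h_true, h_true)
        y = [r[masks["active"]][0] for r in runs]
        res = HrfBasisModel(y, designs, basis_default, basis_default).fit()
        est = res.hrf("novelty")
        r = np.corrcoef(est.h, h_true)[0, 1]
        assert r >= 1 - 1e-8


class TestSummaries:
    def test_gaussian_fwhm(self):
        dt = 0.1
        t = np.arange(0, 20, dt)
        s = 2.0
        h = np.exp(-0.5 * ((t - 8) / s) ** 2)
        amp, lat, fwhm = hrf_summaries(h, dt)
        assert amp == pytest.approx(1.0, abs=1e-6)
        assert lat == pytest.approx(8.0, abs=dt)
        assert fwhm == pytest.approx(2.3548 * s, abs=dt)

    def test_scaling_behaviour(self):
        dt = 0.5
        t = np.arange(0, 24, dt)
        h = np.exp(-0.5 * ((t - 5) / 1.5) ** 2)
        a1, l1, w1 = hrf_summaries(h, dt)
        a2, l2, w2 = hrf_summaries(2 * h, dt)
        assert a2 == pytest.approx(2 * a1)
        assert l2 == l1 and w2 == pytest.approx(w1)

    def test_negative_lobe_amplitude_signed(self):
        dt = 0.5
        t = np.arange(0, 24, dt)
        h = -np.exp(-0.5 * ((t - 6) / 2) ** 2)
        amp, lat, _ = hrf_summaries(h, dt)
        assert amp == pytest.approx(-1.0, abs=1e-6)
        assert lat == pytest.approx(6.0, abs=dt)

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            hrf_summaries(np.ones(10), 2.0)


class TestCvAndSelection:
    def test_noiseless_correct_basis_zero_error(self, designs, basis_default,
                                                span_truth):
        h_true, _ = span_truth
        runs, masks = noiseless_runs(designs, h_true, h_true)
        y = [r[masks["active"]][0] for r in runs]
        err = cv_generalization_error(y, designs, 2, basis_default.alpha,
                                      basis_default.tau)
        assert err <= 1e-12

    def test_single_run_rejected(self, designs):
        with pytest.raises(ValueError, match="2 runs"):
            cv_generalization_error([np.zeros(127)], designs[:1], 2, 1.0, 0.0)

    def test_pure_noise_cv_converges_to_noise_floor(self, designs):
        rng = np.random.default_rng(4)
        sigma = 0.8
        y = [rng.normal(0, sigma, 127) for _ in range(6)]
        err = cv_generalization_error(y, designs, 2, 1.0, 1.0)
        assert err == pytest.approx(sigma**2, rel=0.05)

    def test_wrong_alpha_increases_cv_error(self, designs, span_truth):
        h_true, _ = span_truth
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            gt = GroundTruth(
                hrf_nov=h_true, hrf_rep=h_true,
                noise=NoiseSpec(white_sd=0.2, ar1=0.0, drift_slope=0.0,
                                physio_amps=(0.0,)))
            runs = [simulate_bold_run(d, gt, grid_shape=(10, 10, 7),
                                      seed=1000 * s + i)[0]
                    for i, d in enumerate(designs)]
            masks_ = simulate_bold_run(designs[0], gt, grid_shape=(10, 10, 7),
                                       seed=0)[2]
            y = [r[masks_["active"]][0] for r in runs]
            good = cv_generalization_error(y, designs, 2, 1.0, 1.0)
            bad = cv_generalization_error(y, designs, 2, 3.0, 4.0)
            wins += bad > good
        assert wins >= 95

    def test_grid_single_point_returned(self, designs):
        y = [np.random.default_rng(i).normal(size=127) for i in range(2)]
        a, t, surf = grid_search_basis([y], designs[:2], 2, [0.7], [1.3])
        assert (a, t) == (0.7, 1.3) and surf.shape == (1, 1)

    def test_flat_zero_signal_tie_break(self, designs):
        y = [np.zeros(127) for _ in range(2)]
        a, t, _ = grid_search_basis([y], designs[:2], 2, [2.0, 0.5],
                                    [1.0, 0.0])
        assert (a, t) == (0.5, 0.0)  # smallest tau, then smallest alpha

    def test_bic_prefers_smaller_order_on_equal_rss(self):
        # identical RSS: penalty monotone in parameter count
        n = 100
        assert (n * np.log(0.5) + 2 * np.log(n)
                < n * np.log(0.5) + 4 * np.log(n))

    def test_order_selection_on_pure_noise_picks_smallest(self, designs):
        picks = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            y = [rng.normal(size=127) for _ in range(6)]
            picks.append(select_model_order(y, designs, 1.0, 1.0,
                                            L_candidates=(1, 2, 3)))
        assert np.mean(np.array(picks) == 1) > 0.5

    def test_empty_candidates_rejected(self, designs):
        with pytest.raises(ValueError):
            select_model_order([np.zeros(127)] * 2, designs[:2], 1.0, 1.0,
                               L_candidates=())


class TestGroupShape:
    def test_identical_curves(self, span_truth):
        h, _ = span_truth
        res = group_hrf_shape([h] * 5)
        r = np.corrcoef(res.curve, h)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert res.explained_variance == pytest.approx(1.0, abs=1e-12)

    def test_jittered_curves_high_correlation(self, span_truth):
        h, _ = span_truth
        rng = np.random.default_rng(0)
        curves = [h + rng.normal(0, 0.01 * np.abs(h).max(), len(h))
                  for _ in range(20)]
        res = group_hrf_shape(curves)
        assert abs(np.corrcoef(res.curve, h)[0, 1]) >= 0.99

    def test_antisymmetric_pair_sign_convention(self, span_truth):
        h, _ = span_truth
        res = group_hrf_shape([h, -h])
        assert res.curve[np.argmax(np.abs(res.curve))] > 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            group_hrf_shape([np.ones(5), np.ones(6)])


class TestEquivariance:
    def test_y_scaling_scales_amplitudes(self, designs, basis_default,
                                         span_truth):
        h_true, _ = span_truth
        runs, masks = noiseless_runs(designs, h_true, h_true)
        y = [r[masks["active"]][0] + 0.3 for r in runs]
        res1 = HrfBasisModel(y, designs, basis_default, basis_default).fit()
        res2 = HrfBasisModel([3.0 * yy for yy in y], designs, basis_default,
                             basis_default).fit()
        a1 = res1.hrf("novelty").amplitude
        a2 = res2.hrf("novelty").amplitude
        assert a2 == pytest.approx(3.0 * a1, rel=1e-12)
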