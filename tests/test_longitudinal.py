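"""Composites, mixed-model inference, clustering, floodlight, ICC."""

import numpy as np
import pandas as pd
import pytest

from lcpipe import longitudinal as lng
from lcpipe.simulate import simulate_cohort


def subtest_table(n_sub=20, n_visits=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        base = rng.normal(0, 1, 5)
        for v in range(n_visits):
            scores = base + rng.normal(0, 0.3, 5) - 0.1 * v
            rows.append({"subject": s, "time_years": float(v),
                         **dict(zip(lng.PACC5_SUBTESTS, scores))})
    return pd.DataFrame(rows)


class TestPacc5:
    def test_baseline_mean_is_zero(self):
        tab = subtest_table()
        pacc = lng.compute_pacc5(tab)
        base = pacc[np.isclose(tab["time_years"], 0.0)]
        assert abs(base.mean()) <= 1e-12

    def test_subject_at_baseline_means_scores_zero(self):
        tab = subtest_table()
        base = tab[tab.time_years == 0]
        ref = {k: (base[k].mean(), base[k].std(ddof=1))
               for k in lng.PACC5_SUBTESTS}
        row = pd.DataFrame([{"subject": 99, "time_years": 0.0,
                             **{k: ref[k][0] for k in lng.PACC5_SUBTESTS}}])
        assert lng.compute_pacc5(row, baseline_reference=ref)[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_one_missing_subtest_allowed(self):
        ref = {k: (0.0, 1.0) for k in lng.PACC5_SUBTESTS}
        row = pd.DataFrame([{"subject": 0, "time_years": 1.0,
                             "dsst": 1.0, "fcsrt": 1.0, "logical_memory": 1.0,
                             "mmse": 1.0, "category_fluency": np.nan}])
        assert lng.compute_pacc5(row, baseline_reference=ref)[0] == \
            pytest.approx(1.0)

    def test_two_missing_subtests_give_missing(self):
        ref = {k: (0.0, 1.0) for k in lng.PACC5_SUBTESTS}
        row = pd.DataFrame([{"subject": 0, "time_years": 1.0,
                             "dsst": 1.0, "fcsrt": 1.0, "logical_memory": 1.0,
                             "mmse": np.nan, "category_fluency": np.nan}])
        assert np.isnan(lng.compute_pacc5(row, baseline_reference=ref)[0])

    def test_zero_baseline_sd_rejected(self):
        tab = subtest_table()
        tab.loc[tab.time_years == 0, "mmse"] = 30.0
        with pytest.raises(ValueError, match="mmse"):
            lng.compute_pacc5(tab)

    def test_executive_composite_flips_trails(self):
        ref = {k: (0.0, 1.0) for k in lng.EXECUTIVE_SUBTESTS}
        row = pd.DataFrame([{"time_years": 1.0, "trails_b_minus_a": 2.0,
                             "letter_number": 0.0, "fas_fluency": 0.0}])
        comp = lng.compute_composite(row, lng.EXECUTIVE_SUBTESTS,
                                     baseline_reference=ref)
        assert comp[0] == pytest.approx(-2.0 / 3.0)


class TestPairedAmplitudeTest:
    def test_identical_amplitudes(self):
        with pytest.raises(ValueError):
            lng.paired_amplitude_test([1, 2, 3], [1, 2, 3])

    def test_equal_means_zero_t(self):
        t, df, p = lng.paired_amplitude_test([1.0, 2.0, 3.0, 4.0],
                                             [2.0, 1.0, 4.0, 3.0])
        assert t == pytest.approx(0.0) and df == 3 and p == pytest.approx(1.0)

    def test_power_and_type_I(self):
        rng = np.random.default_rng(0)
        n_rep, n = 2000, 4
        rej_alt = rej_null = 0
        for _ in range(n_rep):
            d_alt = 1.0 + rng.normal(0, 0.1, n)
            d_null = rng.normal(0, 1.0, n)
            rej_alt += lng.paired_amplitude_test(d_alt, np.zeros(n))[2] < 0.05
            rej_null += lng.paired_amplitude_test(d_null, np.zeros(n))[2] < 0.05
        assert rej_alt / n_rep >= 0.99
        assert rej_null / n_rep == pytest.approx(0.05, abs=0.01)


class TestLmeModel:
    def test_degenerate_noiseless_fit_exact(self):
        coh = simulate_cohort(40, {"b9": 0.3, "b11": 0.15, "b4": 0.5},
                              random_effect_sds=(0, 0, 0, 0), seed=1)
        spec = lng.LmeSpec(model="ii", prune_covariate_interactions=False,
                           random_slope=False)
        res = lng.LongitudinalInteractionModel.from_dataframe(coh, spec).fit()
        assert res.params["pred:time_years"] == pytest.approx(0.3, abs=1e-6)
        assert res.params["pred:_pib:time_years"] == pytest.approx(0.15,
                                                                   abs=1e-6)
        assert res.params["pred"] == pytest.approx(0.5, abs=1e-6)

    def test_dichotomous_pib_sign_agrees_with_continuous(self):
        agree = both = 0
        for s in range(25):
            coh = simulate_cohort(150, {"b11": 0.4}, seed=600 + s)
            res_c = lng.LongitudinalInteractionModel.from_dataframe(
                coh, lng.LmeSpec(model="ii", pib_mode="continuous",
                                 prune_covariate_interactions=False)).fit()
            res_d = lng.LongitudinalInteractionModel.from_dataframe(
                coh, lng.LmeSpec(model="ii", pib_mode="dichotomous",
                                 prune_covariate_interactions=False)).fit()
            zc = res_c.zvalues["pred:_pib:time_years"]
            zd = res_d.zvalues["pred:_pib:time_years"]
            if abs(zc) > 1.96 and abs(zd) > 1.96:
                both += 1
                agree += np.sign(res_c.params["pred:_pib:time_years"]) == \
                    np.sign(res_d.params["pred:_pib:time_years"])
        assert both > 0
        assert agree / both >= 0.95

    def test_pruning_drops_weak_covariate_interactions(self):
        coh = simulate_cohort(150, {"b9": 0.2}, seed=2)
        res = lng.LongitudinalInteractionModel.from_dataframe(
            coh, lng.LmeSpec(model="ii")).fit()
        # generating covariate-by-time effects are zero, so pruning should
        # usually remove them while keeping the predictor terms
        assert "pred:time_years" in res.params.index
        for t in res.pruned_terms:
            assert t.endswith("time_years") and not t.startswith("pred")


class TestSimpleSlopesAndFloodlight:
    @pytest.fixture(scope="class")
    def fitted(self):
        coh = simulate_cohort(200, {"b9": 0.1, "b11": 0.5}, seed=3)
        spec = lng.LmeSpec(model="ii", prune_covariate_interactions=False)
        return lng.LongitudinalInteractionModel.from_dataframe(coh, spec).fit()

    def test_slope_linear_combination_identity(self):
        coh = simulate_cohort(120, {"b9": 0.4}, seed=4)
        spec = lng.LmeSpec(model="i", prune_covariate_interactions=False)
        res = lng.LongitudinalInteractionModel.from_dataframe(coh, spec).fit()
        tab = res.simple_slopes("pred", levels=[2.0])
        expect = (res.params["time_years"]
                  + 2.0 * res.params["pred:time_years"])
        assert tab["slope"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_no_interaction_flat_moderation(self):
        coh = simulate_cohort(300, {"b9": 0.2, "b11": 0.0}, seed=5)
        spec = lng.LmeSpec(model="ii", prune_covariate_interactions=False)
        res = lng.LongitudinalInteractionModel.from_dataframe(coh, spec).fit()
        tab = res.simple_slopes("_pib", at={"pred": 1.0})
        lo, hi = tab["slope"].iloc[0], tab["slope"].iloc[-1]
        pooled = np.hypot(tab["se"].iloc[0], tab["se"].iloc[-1])
        assert abs(hi - lo) <= 2 * pooled

    def test_unknown_moderator_rejected(self, fitted):
        with pytest.raises(ValueError, match="moderator"):
            fitted.simple_slopes("not_a_column")

    def test_floodlight_region_within_grid(self, fitted):
        fl = fitted.floodlight()
        assert fl.grid.min() <= fl.region_min <= fl.grid.max()
        assert fl.significant.dtype == bool

    def test_huge_effect_no_noise_full_grid(self):
        coh = simulate_cohort(100, {"b9": 5.0, "b11": 5.0},
                              random_effect_sds=(0.1, 0.02, 0, 0.05), seed=6)
        spec = lng.LmeSpec(model="ii", prune_covariate_interactions=False,
                           random_slope=False)
        res = lng.LongitudinalInteractionModel.from_dataframe(coh, spec).fit()
        fl = res.floodlight()
        assert fl.significant.all()
        assert fl.region_min == pytest.approx(fl.grid.min())

    def test_empty_grid_rejected(self, fitted):
        with pytest.raises(ValueError, match="grid"):
            fitted.floodlight(grid=[])


class TestFdr:
    def test_step_up_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.9])
        # direct BH step-up oracle: largest k with p_(k) <= q k / m
        q, m = 0.05, len(p)
        order = np.argsort(p)
        thresh = q * (np.arange(1, m + 1)) / m
        below = np.flatnonzero(np.sort(p) <= thresh)
        k = below.max() + 1 if below.size else 0
        expect = np.zeros(m, dtype=bool)
        expect[order[:k]] = True
        got = lng.fdr_adjust(p, q)
        assert np.array_equal(got, expect)
        assert got.sum() == 2 and got[0] and got[1]

    def test_all_ones_no_rejections(self):
        assert not lng.fdr_adjust(np.ones(10), 0.05).any()

    def test_monotone_rejection_set(self):
        rng = np.random.default_rng(7)
        p = rng.random(50) ** 2
        rej = lng.fdr_adjust(p, 0.1)
        if rej.any():
            pmax = p[rej].max()
            assert rej[p <= pmax].all()

    def test_nan_excluded(self):
        p = np.array([0.001, np.nan, 0.9])
        rej = lng.fdr_adjust(p, 0.05)
        assert rej[0] and not rej[1] and not rej[2]


class TestClusterFwer:
    def test_all_zero_maps_no_clusters(self):
        maps = np.zeros((8, 10, 10, 7))
        res = lng.cluster_extent_fwer(maps, cdt_z=3.1, n_permutations=100)
        assert len(res.sizes) == 0

    def test_injected_blob_detected(self):
        rng = np.random.default_rng(8)
        truth = np.zeros((12, 12, 8), dtype=bool)
        truth[4:8, 4:8, 3:6] = True
        hits = 0
        for rep in range(10):
            maps = rng.normal(0, 1, size=(40, 12, 12, 8))
            maps[:, truth] += 1.5
            res = lng.cluster_extent_fwer(maps, cdt_z=3.1,
                                          n_permutations=200, seed=rep)
            sig = res.significant(0.05)
            hits += np.any(sig & truth)
        assert hits >= 9

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning, match="permutations"):
            lng.cluster_extent_fwer(np.random.default_rng(0).normal(
                size=(6, 10, 10, 7)), cdt_z=4.5, n_permutations=50)


class TestVoxelwiseLme:
    def test_recovers_planted_effect_per_voxel(self):
        n_sub = 80
        coh = simulate_cohort(n_sub, seed=9)
        rng = np.random.default_rng(9)
        pred = rng.normal(size=(n_sub, 3))
        out = lng.fit_voxelwise_lme(pred, coh,
                                    lng.LmeSpec(model="i",
                                                prune_covariate_interactions=False))
        assert out.shape[0] == 3
        assert ("pred:time_years", "z") in out.columns

    def test_gls_zmap_close_to_full_ml(self):
        n_sub = 100
        coh = simulate_cohort(n_sub, seed=10)
        rng = np.random.default_rng(10)
        pred = rng.normal(size=(n_sub, 4))
        spec = lng.LmeSpec(model="ii", prune_covariate_interactions=False)
        full = lng.fit_voxelwise_lme(pred, coh, spec)
        z_full = full[("pred:_pib:time_years", "z")].to_numpy()
        z_gls = lng.gls_voxel_zmap(pred, coh, spec)
        assert np.max(np.abs(z_full - z_gls)) < 0.35
        assert np.corrcoef(z_full, z_gls)[0, 1] > 0.99


class TestIcc:
    def test_perfect_reliability(self):
        df = pd.DataFrame({"subject": np.repeat(np.arange(10), 3),
                           "score": np.repeat(np.arange(10.0), 3)})
        assert lng.icc_reliability(df) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(500):
            df = pd.DataFrame({"subject": np.repeat(np.arange(12), 3),
                               "score": rng.normal(size=36)})
            vals.append(lng.icc_reliability(df))
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * mc_se

    def test_equal_variance_components_give_half(self):
        rng = np.random.default_rng(12)
        n, k = 500, 4
        subj = rng.normal(0, 1.0, n)
        scores = subj[:, None] + rng.normal(0, 1.0, (n, k))
        df = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                           "score": scores.ravel()})
        assert lng.icc_reliability(df) == pytest.approx(0.5, abs=0.05)

    def test_matches_pingouin_icc3(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        n, k = 30, 3
        scores = (rng.normal(0, 1, n)[:, None] + rng.normal(0, 0.5, (n, k)))
        df = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                           "visit": np.tile(np.arange(k), n),
                           "score": scores.ravel()})
        ours = lng.icc_reliability(df)
        ref = pg.intraclass_corr(data=df, targets="subject", raters="visit",
                                 ratings="score")
        icc3 = ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0]
        assert ours == pytest.approx(float(icc3), abs=1e-8)

    def test_single_visit_subjects_excluded(self):
        df = pd.DataFrame({"subject": [0, 0, 1, 1, 2],
                           "score": [1.0, 1.1, 2.0, 2.1, 5.0]})
        val = lng.icc_reliability(df)
        assert np.isfinite(val)
        with pytest.raises(ValueError):
            lng.icc_reliability(pd.DataFrame({"subject": [0, 1],
                                              "score": [1.0, 2.0]}))
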