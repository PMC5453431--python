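"""Agreement statistics against hand computations and enumeration oracles."""

import itertools

import numpy as np
import pytest

from gaitspeed.evaluation import (
    agreement_regression,
    agreement_report,
    bland_altman,
    clinical_validity_report,
    error_score_correlation,
    fall_group_test,
    grouped_agreement,
    impairment_group,
    loso_evaluate,
    rmse,
    speed_score_correlation,
    transfer_evaluate,
)
from gaitspeed.io import SubjectRecord
from gaitspeed.model import TestPrediction as Prediction


def _preds(pairs):
    """pairs of (estimate, truth) -> single-window TestPredictions."""
    return [Prediction(f"S{i}", "T1", [est], truth)
            for i, (est, truth) in enumerate(pairs)]


class TestRmse:
    def test_perfect_agreement_is_zero(self):
        assert rmse(_preds([(1.0, 1.0), (0.5, 0.5)])) == 0.0

    def test_single_pair(self):
        assert rmse(_preds([(1.1, 1.0)])) == pytest.approx(0.1)

    def test_hand_computed_pair(self):
        assert rmse(_preds([(1.2, 1.0), (0.8, 1.0)])) == pytest.approx(0.2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rmse([])

    def test_rmse_decomposition(self):
        # RMSE^2 = bias^2 + population variance of errors
        rng = np.random.default_rng(8)
        pairs = [(t + rng.normal(0.05, 0.1), t)
                 for t in rng.uniform(0.5, 1.5, 40)]
        preds = _preds(pairs)
        d = np.array([p.error for p in preds])
        assert rmse(preds) ** 2 == pytest.approx(
            d.mean() ** 2 + d.var(ddof=0), abs=1e-9)


class TestBlandAltman:
    def test_hand_computed_symmetric_differences(self):
        # d = {-0.1, 0, 0.1}: sample SD is 0.1, LOA = +/-0.196
        preds = _preds([(0.9, 1.0), (1.0, 1.0), (1.1, 1.0)])
        bias, lo, hi = bland_altman(preds)
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-0.196)
        assert hi == pytest.approx(0.196)

    def test_constant_difference_collapses_loa(self):
        preds = _preds([(1.05, 1.0), (1.25, 1.2), (0.85, 0.8)])
        bias, lo, hi = bland_altman(preds)
        assert bias == pytest.approx(0.05)
        assert lo == pytest.approx(0.05) and hi == pytest.approx(0.05)

    def test_sign_flip_mirrors_loa(self):
        pairs = [(1.1, 1.0), (0.95, 1.0), (1.3, 1.2)]
        flipped = [(t - (e - t), t) for e, t in pairs]
        b1, lo1, hi1 = bland_altman(_preds(pairs))
        b2, lo2, hi2 = bland_altman(_preds(flipped))
        assert b2 == pytest.approx(-b1)
        assert lo2 == pytest.approx(-hi1) and hi2 == pytest.approx(-lo1)

    def test_loa_bracket_bias_and_cover_95pct(self):
        rng = np.random.default_rng(9)
        pairs = [(t + rng.normal(0.02, 0.1), t)
                 for t in rng.uniform(0.3, 1.7, 1000)]
        preds = _preds(pairs)
        bias, lo, hi = bland_altman(preds)
        assert lo <= bias <= hi
        d = np.array([p.error for p in preds])
        inside = ((d >= lo) & (d <= hi)).mean()
        assert inside == pytest.approx(0.95, abs=0.02)

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            bland_altman(_preds([(1.0, 1.0)]))


class TestAgreementRegression:
    def test_identity_data(self):
        preds = _preds([(0.5, 0.5), (1.0, 1.0), (1.5, 1.5)])
        reg = agreement_regression(preds, n_boot=50, seed=0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_collinear_offset_line(self):
        preds = _preds([(0.0, 0.1), (1.0, 1.1), (2.0, 2.1)])
        reg = agreement_regression(preds, n_boot=50, seed=0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.1)

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(10)
        est = rng.uniform(0.3, 1.8, 25)
        truth = 0.92 * est + 0.07 + rng.normal(0, 0.05, 25)
        reg = agreement_regression(_preds(zip(est, truth)), n_boot=10, seed=0)
        m_o, b_o = np.polyfit(est, truth, 1)
        assert reg.slope == pytest.approx(m_o, abs=1e-9)
        assert reg.intercept == pytest.approx(b_o, abs=1e-9)

    def test_zero_estimate_variance_raises(self):
        with pytest.raises(ValueError):
            agreement_regression(_preds([(1.0, 0.9), (1.0, 1.1), (1.0, 1.0)]))

    def test_band_contains_point_fit(self):
        rng = np.random.default_rng(11)
        est = rng.uniform(0.3, 1.8, 30)
        truth = est + rng.normal(0, 0.1, 30)
        reg = agreement_regression(_preds(zip(est, truth)), n_boot=200, seed=1)
        grid = np.linspace(0.4, 1.7, 7)
        lo, hi = reg.band(grid)
        line = reg.slope * grid + reg.intercept
        # percentile band of resampled fits must straddle the point fit
        assert (lo <= line + 1e-9).all() and (line <= hi + 1e-9).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        est = rng.uniform(0.3, 1.8, 20)
        truth = est + rng.normal(0, 0.1, 20)
        r1 = agreement_regression(_preds(zip(est, truth)), n_boot=100, seed=5)
        r2 = agreement_regression(_preds(zip(est, truth)), n_boot=100, seed=5)
        np.testing.assert_array_equal(r1.boot_slopes, r2.boot_slopes)

    def test_bootstrap_covers_generative_line(self):
        # y = m0*x + b0 + noise: the 95% CI should contain (m0, b0)
        # in >= 90 of 100 replicates
        m0, b0 = 0.95, 0.04
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(100):
            # 114 test pairs per replicate, the size of a full normal cohort
            est = rng.uniform(0.2, 1.8, 114)
            truth = m0 * est + b0 + rng.normal(0, 0.08, 114)
            reg = agreement_regression(
                _preds(zip(est, truth)), n_boot=1000,
                seed=int(rng.integers(2 ** 31)))
            if (reg.slope_ci[0] <= m0 <= reg.slope_ci[1]
                    and reg.intercept_ci[0] <= b0 <= reg.intercept_ci[1]):
                hits += 1
        assert hits >= 90


class TestImpairmentGrouping:
    @pytest.mark.parametrize("speed,group", [
        (1.1, "Mild"), (1.5, "Mild"),
        (0.9, "Moderate"), (1.0999, "Moderate"), (0.7001, "Moderate"),
        (0.7, "Severe"), (0.3, "Severe"),
    ])
    def test_threshold_mapping(self, speed, group):
        assert impairment_group(speed) == group

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            impairment_group(-0.1)

    def test_grouped_agreement_partitions_and_excludes_missing(self):
        subjects = [
            SubjectRecord("S0", "MS", t25fw_speed=1.3),
            SubjectRecord("S1", "MS", t25fw_speed=0.9),
            SubjectRecord("S2", "MS", t25fw_speed=0.5),
            SubjectRecord("S3", "MS"),  # no T25FW -> excluded
        ]
        preds = []
        for sid in ("S0", "S1", "S2", "S3"):
            preds += [Prediction(sid, f"T{k}", [1.0], 1.05)
                      for k in range(2)]
        out = grouped_agreement(preds, subjects)
        assert {g: v["n_tests"] for g, v in out.items()} == {
            "Mild": 2, "Moderate": 2, "Severe": 2}


class TestScoreCorrelations:
    def test_error_proportional_to_score_is_one(self):
        subjects = [SubjectRecord(f"S{i}", "MS", msws=0.1 * i + 0.2)
                    for i in range(5)]
        preds = [Prediction(f"S{i}", "T1", [1.0 + 0.05 * i], 1.0)
                 for i in range(5)]
        r, p = error_score_correlation(preds, subjects, "msws")
        assert r == pytest.approx(1.0)

    def test_constant_error_raises(self):
        subjects = [SubjectRecord(f"S{i}", "MS", msws=0.1 * i + 0.2)
                    for i in range(5)]
        preds = [Prediction(f"S{i}", "T1", [1.1], 1.0) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            error_score_correlation(preds, subjects, "msws")

    def test_matches_direct_formula_on_hand_pairs(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([0.2, 0.5, 0.4, 0.9])
        r, _ = speed_score_correlation(x, y)
        # direct product-moment formula
        r_o = (((x - x.mean()) * (y - y.mean())).sum()
               / np.sqrt(((x - x.mean()) ** 2).sum()
                         * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(r_o, abs=1e-12)


class TestFallGroupTest:
    def test_separated_groups_exact_p(self):
        # fall {1,2,3} vs no-fall {4,5,6}: U = 0; enumeration of the 20
        # equally likely rank assignments gives two as extreme -> p = 0.1
        speeds = [1, 2, 3, 4, 5, 6]
        fell = [True, True, True, False, False, False]
        diff, U, p = fall_group_test(speeds, fell)
        assert U == 0.0
        assert p == pytest.approx(0.1)
        assert diff == pytest.approx(-3.0)

    def test_exact_p_matches_enumeration_oracle(self):
        speeds = np.array([0.8, 1.1, 0.9, 1.3, 1.25, 1.0, 1.4])
        fell = np.array([True, False, True, False, False, True, False])
        _, U_obs, p = fall_group_test(speeds, fell)
        # brute-force: U distribution over all assignments of 3 of 7
        n1 = 3
        us = []
        for combo in itertools.combinations(range(7), n1):
            grp = speeds[list(combo)]
            rest = np.delete(speeds, list(combo))
            u = sum((g > r) + 0.5 * (g == r) for g in grp for r in rest)
            us.append(u)
        us = np.array(us)
        mu = n1 * (len(speeds) - n1) / 2
        p_oracle = np.mean(np.abs(us - mu) >= np.abs(U_obs - mu) - 1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_groups(self):
        speeds = [1, 2, 3, 1, 2, 3]
        fell = [True, True, True, False, False, False]
        diff, U, p = fall_group_test(speeds, fell)
        assert diff == pytest.approx(0.0)
        assert U == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    def test_hand_mean_difference(self):
        diff, _, _ = fall_group_test([1.0, 1.2, 1.3, 1.5],
                                     [True, True, False, False])
        assert diff == pytest.approx(-0.3)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            fall_group_test([1.0, 1.2], [True, True])


class TestLoso:
    def test_every_subject_held_out_once(self, small_features):
        preds = loso_evaluate(small_features, ("sacrum",), seed=0)
        subjects = {p.subject_id for p in preds}
        assert subjects == set(small_features["subject_id"].unique())
        n_tests = small_features.groupby(
            ["subject_id", "test_id"]).ngroups
        assert len(preds) == n_tests

    def test_two_subjects_two_folds(self, small_features):
        two = small_features[small_features["subject_id"].isin(["H01", "H02"])]
        preds = loso_evaluate(two, ("sacrum",), seed=0)
        assert {p.subject_id for p in preds} == {"H01", "H02"}

    def test_predictions_invariant_to_row_order(self, small_features):
        preds1 = loso_evaluate(small_features, ("sacrum",), seed=0)
        shuffled = small_features.sample(frac=1.0, random_state=3)
        preds2 = loso_evaluate(shuffled, ("sacrum",), seed=0)
        m1 = {(p.subject_id, p.test_id): p.median_estimate for p in preds1}
        m2 = {(p.subject_id, p.test_id): p.median_estimate for p in preds2}
        for key in m1:
            assert m1[key] == pytest.approx(m2[key], abs=1e-9)

    def test_no_leakage_from_held_out_rows(self, small_features):
        # the model scoring a subject must be unchanged when that
        # subject's (held-out) rows are perturbed
        from gaitspeed.model import assemble_design, train

        corrupted = small_features.copy()
        mask = corrupted["subject_id"] == "H01"
        corrupted.loc[mask, "f01"] += 100.0

        def fold_model(ft):
            X, y, groups, _ = assemble_design(
                ft[ft["subject_id"] != "H01"], ("sacrum",))
            return train(X, y, combo=("sacrum",), subjects=np.unique(groups))

        m1 = fold_model(small_features)
        m2 = fold_model(corrupted)
        np.testing.assert_array_equal(m1.svr.support_vectors_,
                                      m2.svr.support_vectors_)
        np.testing.assert_array_equal(m1.svr.dual_coef_, m2.svr.dual_coef_)
        np.testing.assert_array_equal(m1.scaler.mean_, m2.scaler.mean_)
        # and loso's own prediction for H01 comes from exactly that model
        from gaitspeed.model import predict_tests
        loso_preds = [p for p in loso_evaluate(corrupted, ("sacrum",), seed=0)
                      if p.subject_id == "H01"]
        direct = predict_tests(m1, corrupted[mask])
        m_loso = {(p.subject_id, p.test_id): p.median_estimate for p in loso_preds}
        for p in direct:
            assert m_loso[(p.subject_id, p.test_id)] == pytest.approx(
                p.median_estimate, abs=1e-12)

    def test_mean_estimate_increases_with_speed(self, small_features):
        preds = loso_evaluate(small_features, ("sacrum", "thigh", "shank"),
                              seed=0)
        by_speed = {}
        for p in preds:
            if p.truth > 0:
                by_speed.setdefault(p.truth, []).append(p.median_estimate)
        speeds = sorted(by_speed)
        means = [np.mean(by_speed[s]) for s in speeds]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestTransfer:
    def test_transfer_uses_single_model(self, small_features):
        train_ft = small_features[small_features["subject_id"] != "H04"]
        test_ft = small_features[small_features["subject_id"] == "H04"]
        model, preds = transfer_evaluate(train_ft, test_ft, ("sacrum",))
        assert set(model.training_subjects) == {"H01", "H02", "H03"}
        assert all(p.subject_id == "H04" for p in preds)

    def test_report_and_clinical_summary(self, small_features):
        preds = loso_evaluate(small_features, ("sacrum",), seed=0)
        rep = agreement_report(preds, n_boot=100, seed=0)
        assert rep.n_tests == len(preds)
        assert rep.rmse >= abs(rep.bias)
        assert rep.loa[0] <= rep.bias <= rep.loa[1]
        subjects = [SubjectRecord(s, "MS", edss_sr=2.0 + i, msws=0.3 + 0.1 * i,
                                  fell_last_6mo=i % 2 == 0,
                                  t25fw_speed=1.3 - 0.2 * i)
                    for i, s in enumerate(sorted({p.subject_id for p in preds}))]
        out = clinical_validity_report(
            preds, subjects,
            comfortable_test_ids={s.subject_id: "W3" for s in subjects})
        assert "error_vs_edss_sr" in out and "by_impairment_group" in out
        assert "speed_vs_msws" in out and "fall_speed_difference" in out
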