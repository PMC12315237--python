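import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from l2cforecast.cohort import split_half
from l2cforecast.evaluate import (
    EvaluationError,
    ablate_modality,
    bin_by_horizon,
    corrected_resampled_ttest,
    fdr_bh,
    feature_importance_by_ablation,
    has_full_feature_set,
    mae_by_participant,
    match_forecasts,
    mauc,
    paired_ttest,
    permutation_test_mauc,
    run_experiment,
    subgroup_by_last_dx,
)
from l2cforecast.models import ForecastGrid, Prediction
from helpers import make_history, make_visit, pairwise_mauc


def make_grid(last=0.0, horizon=12):
    months = last + np.arange(1, horizon + 1, dtype=float)
    preds = tuple(Prediction(m, (1.0, 0.0, 0.0), 28.0, 0.02) for m in months)
    return ForecastGrid("P1", months, preds)


class TestMatchForecasts:
    def test_nearest_month_and_tie_to_earlier(self):
        grid = make_grid()
        v1 = make_visit(month=10.4, mmse=25.0)
        v2 = make_visit(month=10.5, mmse=25.0)
        pairs, _ = match_forecasts(grid, [v1, v2])
        assert pairs[0][0].month == 10.0
        assert pairs[1][0].month == 10.0  # tie broken toward earlier month

    def test_visits_beyond_horizon_excluded_and_counted(self):
        grid = make_grid(horizon=6)
        pairs, n_excl = match_forecasts(grid, [make_visit(month=3.0, mmse=25.0),
                                               make_visit(month=40.0, mmse=20.0)])
        assert len(pairs) == 1 and n_excl == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            match_forecasts(ForecastGrid("P1", np.array([]), ()), [])


class TestMauc:
    def test_perfect_predictor(self):
        probs = np.eye(3)[[0, 0, 1, 1, 2, 2]]
        truth = [0, 0, 1, 1, 2, 2]
        assert mauc(probs, truth) == 1.0

    def test_constant_predictor_is_chance(self):
        probs = np.full((9, 3), 1 / 3)
        truth = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert mauc(probs, truth) == pytest.approx(0.5)

    def test_six_point_worked_set(self):
        probs = np.array([[.7, .2, .1], [.6, .3, .1], [.2, .5, .3],
                          [.3, .4, .3], [.1, .3, .6], [.2, .2, .6]])
        truth = [0, 0, 1, 1, 2, 2]
        assert mauc(probs, truth) == pytest.approx(1.0)
        swapped = [2, 2, 1, 1, 0, 0]
        assert mauc(probs, swapped) < 0.5

    def test_matches_pairwise_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for n in (20, 90, 200):
            probs = rng.dirichlet([1, 1, 1], size=n)
            truth = rng.integers(0, 3, size=n)
            assert mauc(probs, truth) == pytest.approx(
                pairwise_mauc(probs, truth), abs=1e-12)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet([1, 1, 1], size=60)
        truth = rng.integers(0, 3, size=60)
        warped = np.exp(probs * 3.0)  # strictly monotone per class
        assert mauc(warped, truth) == pytest.approx(mauc(probs, truth), abs=1e-12)

    def test_absent_class_skipped_and_all_absent_rejected(self):
        probs = np.array([[.9, .1, 0.0], [.2, .8, 0.0]])
        assert mauc(probs, [0, 1]) == pytest.approx(1.0)  # DEM skipped
        with pytest.raises(EvaluationError):
            mauc(probs, [0, 0])


class TestMaeByParticipant:
    def test_within_participant_average(self):
        frame = pd.DataFrame({
            "participant_id": ["a", "a", "b"],
            "truth": [10.0, 10.0, 20.0],
            "pred": [11.0, 13.0, 20.0],
        })
        out = mae_by_participant(frame, "truth", "pred")
        assert out["per_participant_mae"]["a"] == 2.0  # mean of {1, 3}
        assert out["per_participant_mae"]["b"] == 0.0
        assert out["mae"] == 1.0
        assert out["per_participant_rmse"]["a"] == pytest.approx(math.sqrt(5))

    def test_participants_without_truth_excluded_and_counted(self):
        frame = pd.DataFrame({
            "participant_id": ["a", "b"],
            "truth": [10.0, np.nan],
            "pred": [10.0, 15.0],
        })
        out = mae_by_participant(frame, "truth", "pred")
        assert out["n_participants"] == 1 and out["n_excluded"] == 1


class TestCorrectedResampledTtest:
    def test_all_zero_diffs(self):
        res = corrected_resampled_ttest(np.zeros(10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_rho_zero_recovers_classical_t(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=15)
        res = corrected_resampled_ttest(d, rho=0.0)
        t, p = stats.ttest_1samp(d, 0.0)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_independent_formula_transcription(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=20)
        k, rho = 20, 1.0 / 19.0
        # independent transcription of the corrected statistic
        t_ref = d.mean() / math.sqrt((1.0 / k + rho) * d.var(ddof=1))
        p_ref = 2.0 * stats.t.sf(abs(t_ref), df=k - 1)
        res = corrected_resampled_ttest(d, rho=rho)
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_nonzero_mean(self):
        res = corrected_resampled_ttest(np.full(5, 0.2))
        assert res.p_value == 0.0


class TestPermutationTest:
    def test_identical_models_give_p_one(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet([1, 1, 1], size=40)
        truth = rng.integers(0, 3, size=40)
        res = permutation_test_mauc(probs, probs, truth, n_perm=99, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_smoothed_p_floor(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, size=60)
        good = np.eye(3)[truth]
        bad = rng.dirichlet([1, 1, 1], size=60)
        res = permutation_test_mauc(good, bad, truth, n_perm=99, seed=0)
        assert res.p_value >= 1.0 / 100.0

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_mauc(np.ones((3, 3)) / 3, np.ones((4, 3)) / 4,
                                  [0, 1, 2], n_perm=9)


class TestFdrBh:
    def test_no_rejections_at_p_one(self):
        assert not fdr_bh(np.ones(5)).any()

    def test_single_small_p_rejected(self):
        assert fdr_bh([0.01]).tolist() == [True]

    def test_step_up_rule_hand_enumerated(self):
        # thresholds i/10 * 0.05: largest i with p_(i) <= threshold is i=4
        p = [0.001, 0.008, 0.012, 0.020, 0.031, 0.042, 0.060, 0.200, 0.440, 0.900]
        flags = fdr_bh(p, q=0.05)
        assert flags.tolist() == [True] * 4 + [False] * 6


class TestHorizonBinning:
    @pytest.mark.parametrize("gap,expected", [
        (10.0, 1), (12.0, 1), (12.1, 2), (24.0, 2), (25.0, 3), (80.0, 6),
    ])
    def test_yearly_bins(self, gap, expected):
        assert bin_by_horizon(60.0, 60.0 + gap) == expected

    def test_non_positive_gap_rejected(self):
        with pytest.raises(ValueError):
            bin_by_horizon(60.0, 60.0)


class TestSubgroups:
    def test_last_observed_input_diagnosis(self):
        visits = [make_visit(month=0.0, diagnosis="CN"),
                  make_visit(month=10.0, diagnosis="MCI"),
                  make_visit(month=20.0)]
        groups, n_excl = subgroup_by_last_dx({"a": visits, "b": [make_visit(month=0.0, mmse=28.0)]})
        assert groups == {"a": "MCI"} and n_excl == 1


class TestAblation:
    def test_mri_ablation_blanks_input_rois_only(self, four_visit_history):
        inp, _ = split_half(four_visit_history)
        out = ablate_modality(four_visit_history, "mri", len(inp))
        for v in out.visits[:len(inp)]:
            assert not v.roi_volumes and not v.roi_normalized
            assert v.mmse is not None and v.diagnosis is not None
        for v, orig in zip(out.visits[len(inp):], four_visit_history.visits[len(inp):]):
            assert v == orig

    def test_unknown_modality_rejected(self, four_visit_history):
        with pytest.raises(ValueError):
            ablate_modality(four_visit_history, "genetics", 2)

    def test_full_feature_set_detection(self, four_visit_history):
        inp, _ = split_half(four_visit_history)
        assert has_full_feature_set(inp)
        blanked = ablate_modality(four_visit_history, "cognitive", len(inp))
        assert not has_full_feature_set(blanked.visits[:len(inp)])

    def test_importance_deltas_zero_for_identical_reports(self):
        from l2cforecast.evaluate import MetricReport
        rep = MetricReport(0.9, 1.0, 0.001, 1.2, 0.0012, 10, 30)
        table = feature_importance_by_ablation(
            {"full": rep, "mri": rep, "cognitive": rep})
        assert (table["delta"] == 0.0).all()
        assert len(table) == 6  # (2 scenarios) x (3 targets)


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def harness_reports(self, small_cohort):
        return run_experiment(small_cohort, "carry_forward", k=3, seed=0,
                              analyses=("main", "horizon", "subgroup"))

    def test_one_main_row_per_fold(self, harness_reports):
        main = harness_reports.query("analysis == 'main'")
        assert len(main) == 3
        assert main["n_participants"].sum() == 60  # test sets cover cohort

    def test_horizon_bins_within_range(self, harness_reports):
        bins = harness_reports.query("analysis == 'horizon'")["stratum"].astype(int)
        assert bins.between(1, 6).all()

    def test_subgroup_counts_reconcile(self, harness_reports):
        for fold, grp in harness_reports.query("analysis == 'subgroup'").groupby("fold"):
            main_n = harness_reports.query(
                "analysis == 'main' and fold == @fold")["n_participants"].iloc[0]
            assert grp["n_participants"].sum() <= main_n

    def test_unknown_analysis_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            run_experiment(small_cohort, "carry_forward", k=3, analyses=("bogus",))


def test_paired_ttest_on_shifted_errors():
    rng = np.random.default_rng(9)
    a = rng.normal(1.0, 0.2, size=30)
    res = paired_ttest(a + 0.5 + rng.normal(0, 0.05, size=30), a)
    assert res.p_value < 1e-6 and res.statistic > 0
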