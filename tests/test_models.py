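import math

import numpy as np
import pytest

from l2cforecast.cohort import split_half
from l2cforecast.features import samples_to_frame
from l2cforecast.models import (
    FNNConfig,
    TrainingError,
    cdr_to_diag_probs,
    default_window_spec,
    forecast_monthly,
    make_carry_forward,
    predict_bundle,
    select_window,
    train_fnn,
    train_xgb,
)


class TestCdrToDiagProbs:
    @pytest.mark.parametrize("cdr,expected", [
        (0.0, (1.0, 0.0, 0.0)),
        (0.1, (0.8, 0.2, 0.0)),
        (0.5, (0.0, 1.0, 0.0)),
        (0.6, (0.0, 0.8, 0.2)),
        (1.0, (0.0, 0.0, 1.0)),
        (2.0, (0.0, 0.0, 1.0)),
        (-0.3, (1.0, 0.0, 0.0)),  # negative clips to 0
    ])
    def test_anchor_and_interpolated_points(self, cdr, expected):
        np.testing.assert_allclose(cdr_to_diag_probs(cdr), expected, atol=1e-12)

    def test_continuous_simplex_on_unit_interval(self):
        grid = np.linspace(0.0, 1.2, 121)
        probs = np.array([cdr_to_diag_probs(c) for c in grid])
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all() and (probs <= 1).all()
        # continuity: small CDR steps give small probability steps
        assert np.abs(np.diff(probs, axis=0)).max() < 0.05

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cdr_to_diag_probs(float("nan"))


class TestSelectWindow:
    @pytest.mark.parametrize("target,gap,expected", [
        ("mmse", 10.0, 1),       # 9-15
        ("mmse", 0.0, 0),
        ("mmse", 9.0, 1),        # closed on left
        ("mmse", 45.0, 3),       # hole (39,54) -> 27-39 model
        ("mmse", 54.0, 4),
        ("diagnosis", 70.0, 5),  # >60
        ("diagnosis", 39.0, 4),
        ("ventricle", 100.0, 3),
    ])
    def test_window_assignment(self, target, gap, expected):
        assert select_window(gap, target, default_window_spec()) == expected

    def test_hole_routes_to_nearest_lower_boundary(self):
        spec = default_window_spec()
        for gap in np.arange(39.0, 54.0, 0.5):
            assert select_window(float(gap), "mmse", spec) == 3

    def test_undefined_gap_yields_no_model(self):
        assert select_window(float("nan"), "mmse", default_window_spec()) is None

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            select_window(-1.0, "mmse", default_window_spec())

    def test_total_model_count(self):
        assert default_window_spec().n_models == 15


class TestTrainXgb:
    def test_unwindowed_bundle_has_three_estimators(self, train_samples):
        bundle = train_xgb(train_samples[:400], seed=0)
        assert bundle.variant == "xgb_nw"
        assert bundle.n_estimators == 3

    def test_windowed_bundle_partitions_samples(self, train_samples):
        bundle = train_xgb(train_samples, windows=default_window_spec(), seed=0)
        assert bundle.n_estimators == 15
        X, y = samples_to_frame(train_samples)
        gaps = X["time_since_mr_mmse"].to_numpy()
        observed = y["mmse"].notna().to_numpy() & np.isfinite(gaps)
        assigned = [select_window(g, "mmse", bundle.windows)
                    for g in gaps[observed]]
        # every covered-gap sample lands in exactly one window
        assert len(assigned) == observed.sum()
        assert all(a is not None for a in assigned)

    def test_hyperparameters_outside_ranges_rejected(self, train_samples):
        for bad in ({"max_depth": 2}, {"subsample": 0.3}, {"learning_rate": 0.5}):
            with pytest.raises(ValueError):
                train_xgb(train_samples[:50], hp=bad)

    def test_empty_window_cell_raises_with_window_name(self):
        # Short-gap-only samples leave long-horizon windows empty.
        short = [s for s in make_short_gap_samples()]
        with pytest.raises(TrainingError, match="window"):
            train_xgb(short, windows=default_window_spec(), seed=0)


def make_short_gap_samples():
    from helpers import make_history
    from l2cforecast.features import augment_training_samples
    samples = []
    for i in range(5):
        h = make_history([dict(month=float(j), mmse=28.0 - j, diagnosis="CN",
                               cdr_global=0.0)
                          for j in range(4)], pid=f"Q{i}")
        samples.extend(augment_training_samples(h))
    return samples


class TestFNN:
    def test_same_seed_reproduces_training(self, train_samples):
        cfg = FNNConfig(epochs=5, seed=3)
        b1 = train_fnn(train_samples[:300], cfg)
        b2 = train_fnn(train_samples[:300], cfg)
        assert b1.estimators["fnn"].loss_history == b2.estimators["fnn"].loss_history
        for w1, w2 in zip(b1.estimators["fnn"].weights, b2.estimators["fnn"].weights):
            np.testing.assert_array_equal(w1, w2)

    def test_masked_loss_ignores_missing_targets(self, train_samples):
        cfg = FNNConfig(epochs=1, seed=0)
        bundle = train_fnn(train_samples[:200], cfg)
        net = bundle.estimators["fnn"]
        X = np.zeros((1, net.n_inputs))
        loss_none, _, _ = net.loss_and_grads(
            X, np.array([-1]), np.array([np.nan]), np.array([np.nan]), rng=None)
        assert loss_none == 0.0
        loss_dx, _, _ = net.loss_and_grads(
            X, np.array([1]), np.array([np.nan]), np.array([np.nan]), rng=None)
        assert loss_dx > 0.0

    def test_prediction_contracts(self, train_samples):
        bundle = train_fnn(train_samples[:400], FNNConfig(epochs=10, seed=1))
        X, y = samples_to_frame(train_samples[400:500])
        preds = predict_bundle(bundle, X, y["target_month"].to_numpy())
        for p in preds:
            assert sum(p.diag_probs) == pytest.approx(1.0, abs=1e-6)
            assert 0.0 <= p.mmse <= 30.0
            assert p.ventricle_icv >= 0.0

    def test_batch_prediction_equals_rowwise(self, train_samples):
        bundle = train_fnn(train_samples[:300], FNNConfig(epochs=5, seed=2))
        X, y = samples_to_frame(train_samples[300:330])
        months = y["target_month"].to_numpy()
        batch = predict_bundle(bundle, X, months)
        for i in range(len(X)):
            single = predict_bundle(bundle, X.iloc[[i]], months[[i]])[0]
            np.testing.assert_allclose(single.diag_probs, batch[i].diag_probs,
                                       atol=1e-12)
            assert single.mmse == pytest.approx(batch[i].mmse)

    def test_no_observed_targets_rejected(self, train_samples):
        import dataclasses
        stripped = [dataclasses.replace(s, diagnosis=None, mmse=None,
                                        ventricle_icv=None)
                    for s in train_samples[:20]]
        with pytest.raises(TrainingError):
            train_fnn(stripped, FNNConfig(epochs=1))

    def test_config_range_validation(self):
        with pytest.raises(ValueError):
            FNNConfig(n_hidden_layers=1)
        with pytest.raises(ValueError):
            FNNConfig(lr_gamma=0.95)


class TestForecastMonthly:
    def test_grid_shape_and_month_spacing(self, train_samples, small_cohort):
        bundle = train_xgb(train_samples[:400], seed=0)
        h = small_cohort[0]
        grid = forecast_monthly(bundle, h, horizon_months=120)
        assert len(grid.predictions) == 120
        np.testing.assert_allclose(np.diff(grid.months), 1.0)
        assert grid.months[0] == h.visits[-1].month + 1

    def test_forecast_determinism(self, train_samples, small_cohort):
        bundle = train_xgb(train_samples[:400], seed=0)
        h = small_cohort[1]
        g1 = forecast_monthly(bundle, h, 24)
        g2 = forecast_monthly(bundle, h, 24)
        for p1, p2 in zip(g1.predictions, g2.predictions):
            assert p1 == p2

    def test_windowed_forecast_unavailable_when_target_never_observed(
            self, train_samples):
        from helpers import make_history
        bundle = train_xgb(train_samples, windows=default_window_spec(), seed=0)
        # History with diagnosis and CDR only: MMSE and ventricle never observed.
        h = make_history([dict(month=0.0, diagnosis="MCI", cdr_global=0.5),
                          dict(month=8.0, diagnosis="MCI", cdr_global=0.5)])
        grid = forecast_monthly(bundle, h, 6)
        for p in grid.predictions:
            assert p.mmse is None
            assert p.ventricle_icv is None
            assert p.diag_probs is not None


class TestCarryForward:
    def test_last_observation_repeated(self, four_visit_history):
        bundle = make_carry_forward()
        inp, _ = split_half(four_visit_history)
        grid = forecast_monthly(bundle, four_visit_history, 36, inp)
        for p in grid.predictions:
            assert p.diag_probs == (1.0, 0.0, 0.0)  # last input dx is CN
            assert p.mmse == 28.0                   # last input MMSE
            assert p.ventricle_icv == pytest.approx(33000.0 / 1500000.0)

    def test_median_fallback_when_never_observed(self, train_samples):
        from helpers import make_history
        bundle = make_carry_forward(train_samples)
        h = make_history([dict(month=0.0, diagnosis="DEM"),
                          dict(month=9.0, diagnosis="DEM")])
        p = forecast_monthly(bundle, h, 1).predictions[0]
        assert p.diag_probs == (0.0, 0.0, 1.0)
        assert p.mmse == pytest.approx(bundle.medians["mmse"], abs=1e-9)
        assert p.ventricle_icv == pytest.approx(bundle.medians["ventricle"])

    def test_uniform_diagnosis_when_never_observed(self):
        from helpers import make_history
        bundle = make_carry_forward()
        h = make_history([dict(month=0.0, mmse=27.0), dict(month=7.0, mmse=26.0)])
        p = forecast_monthly(bundle, h, 1).predictions[0]
        np.testing.assert_allclose(p.diag_probs, [1 / 3] * 3)
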