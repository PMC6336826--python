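"""Count-to-seconds calibration and report metrics."""

import numpy as np
import pandas as pd
import pytest

from perceptime.calibration import (
    CalibrationSpec,
    EstimateSet,
    compute_nme,
    compute_rmse,
    fit_and_predict_cv,
    scene_bias_deviations,
    variance_by_duration,
)
from perceptime.synthetic import STANDARD_DURATIONS_S
from perceptime.thresholds import AccumulatorVector

RATES = (2.0, 1.0, 0.5, 0.1)


def proportional_accumulators(repetitions=20, rates=RATES, scenes=("a", "b")):
    """Counts exactly proportional to duration, one rate per layer."""
    accs = []
    for d in STANDARD_DURATIONS_S:
        for rep in range(repetitions):
            accs.append(
                AccumulatorVector(
                    counts={f"L{i}": int(round(r * d)) for i, r in enumerate(rates)},
                    trial_id=f"d{d:g}_r{rep:03d}",
                    duration_s=float(d),
                    scene_type=scenes[rep % len(scenes)],
                )
            )
    return accs


def estimate_set(true_s, predicted_s, scene=None, fold=None):
    n = len(true_s)
    return EstimateSet(
        pd.DataFrame(
            {
                "trial_id": [f"t{i}" for i in range(n)],
                "regime": "test",
                "scene_type": scene if scene is not None else ["s"] * n,
                "true_s": np.asarray(true_s, float),
                "predicted_s": np.asarray(predicted_s, float),
                "predicted_clamped_s": np.maximum(predicted_s, 0.0),
                "fold": fold if fold is not None else np.zeros(n, int),
            }
        )
    )


class TestCrossValidation:
    def test_every_trial_in_exactly_one_test_fold(self):
        accs = proportional_accumulators(repetitions=3)
        est = fit_and_predict_cv(accs, CalibrationSpec(fold_seed=0))
        assert len(est) == len(accs)
        assert est.frame["trial_id"].is_unique
        sizes = est.frame["fold"].value_counts()
        assert len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1

    def test_proportional_counts_recover_duration_ranking(self):
        """Monotone recovery: noise-free proportional counts rank durations."""
        est = fit_and_predict_cv(proportional_accumulators(), CalibrationSpec(fold_seed=0))
        assert est.rank_correlation() > 0.95

    def test_constant_features_predict_within_target_range(self):
        accs = [
            AccumulatorVector(
                counts={"L0": 5}, trial_id=f"t{i}", duration_s=float(d)
            )
            for i, d in enumerate(np.repeat(STANDARD_DURATIONS_S, 2))
        ]
        est = fit_and_predict_cv(accs, CalibrationSpec(fold_seed=0))
        assert est.frame["predicted_s"].between(1.0, 64.0).all()

    def test_result_invariant_to_trial_ordering(self, rng):
        accs = proportional_accumulators(repetitions=2)
        est1 = fit_and_predict_cv(accs, CalibrationSpec(fold_seed=3))
        shuffled = [accs[i] for i in rng.permutation(len(accs))]
        est2 = fit_and_predict_cv(shuffled, CalibrationSpec(fold_seed=3))
        pd.testing.assert_frame_equal(est1.frame, est2.frame)

    def test_fewer_trials_than_folds_rejected(self):
        accs = proportional_accumulators(repetitions=1)[:5]
        with pytest.raises(ValueError, match="n_folds"):
            fit_and_predict_cv(accs, CalibrationSpec())

    def test_restricted_training_range_compresses_outside_predictions(self):
        """Training only on short durations pulls long estimates down."""
        accs = proportional_accumulators()
        est = fit_and_predict_cv(
            accs, CalibrationSpec(fold_seed=0), train_duration_range=(1.0, 16.0)
        )
        long = est.frame[est.frame["true_s"] > 16.0]
        assert (long.groupby("true_s")["predicted_s"].mean() < long.groupby("true_s")["true_s"].mean()).all()

    def test_capacity_preserving_penalty_scaling(self):
        spec = CalibrationSpec(penalty_reference_n=4290)
        assert spec.effective_penalty(4290) == pytest.approx(1e-3)
        assert spec.effective_penalty(234) == pytest.approx(1e-3 * 4290 / 234)
        assert CalibrationSpec().effective_penalty(234) == pytest.approx(1e-3)


class TestNME:
    def test_perfect_predictions_give_zero(self):
        est = estimate_set([1, 2, 4], [1, 2, 4])
        out = compute_nme(est)
        assert out["nme_overall"] == pytest.approx(0.0)

    def test_doubling_gives_plus_one(self):
        est = estimate_set([1, 2, 4], [2, 4, 8])
        assert compute_nme(est)["nme_overall"] == pytest.approx(1.0)

    def test_mixed_toy_set_hand_arithmetic(self):
        # per-trial errors +1.0 and -0.5; equal weight per duration level
        est = estimate_set([1, 4], [2, 2])
        out = compute_nme(est)
        assert out["nme_per_duration"][1.0] == pytest.approx(1.0)
        assert out["nme_per_duration"][4.0] == pytest.approx(-0.5)
        assert out["nme_overall"] == pytest.approx(0.25)

    def test_duration_levels_weighted_equally_not_by_trials(self):
        # three trials at 1 s, one at 4 s: overall is still the mean of levels
        est = estimate_set([1, 1, 1, 4], [2, 2, 2, 2])
        assert compute_nme(est)["nme_overall"] == pytest.approx((1.0 - 0.5) / 2)

    def test_zero_true_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_nme(estimate_set([0.0], [1.0]))


class TestRMSE:
    def test_perfect_predictions_give_zero(self):
        assert compute_rmse(estimate_set([1, 2], [1, 2])) == pytest.approx(0.0)

    def test_constant_offset_gives_offset(self):
        assert compute_rmse(estimate_set([1, 2, 3], [2, 3, 4])) == pytest.approx(1.0)

    def test_external_reference_series(self):
        est = estimate_set([1, 2], [3, 4])
        assert compute_rmse(est, reference=[3, 4]) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="length"):
            compute_rmse(est, reference=[3.0])


class TestSceneBias:
    def test_identical_scene_distributions_give_zero(self):
        est = estimate_set(
            [1, 1, 4, 4], [2, 2, 5, 5], scene=["a", "b", "a", "b"]
        )
        out = scene_bias_deviations(est)
        assert out["scene_deviation_pct"]["a"] == pytest.approx(0.0)
        assert out["scene_deviation_pct"]["b"] == pytest.approx(0.0)

    def test_ten_percent_uplift_measures_plus_ten(self):
        # scene a sits 10% above the grand mean at every duration level
        est = estimate_set(
            [1, 1, 4, 4], [2.2, 1.8, 5.5, 4.5], scene=["a", "b", "a", "b"]
        )
        out = scene_bias_deviations(est)
        assert out["scene_deviation_pct"]["a"] == pytest.approx(10.0)
        assert out["scene_deviation_pct"]["b"] == pytest.approx(-10.0)
        assert out["scene_order"] == ["a", "b"]

    def test_trialcount_weighted_deviations_sum_to_zero_per_duration(self, rng):
        scenes = list("abc")
        true = np.repeat([1.0, 4.0, 8.0], 9)
        scene = np.tile(np.repeat(scenes, 3), 3)
        pred = true * rng.uniform(0.5, 1.5, size=len(true))
        out = scene_bias_deviations(estimate_set(true, pred, scene=list(scene)))
        table = out["per_duration"]
        for _, g in table.groupby("true_s"):
            weighted = np.average(g["deviation_pct"], weights=g["n_trials"])
            assert weighted == pytest.approx(0.0, abs=1e-9)

    def test_single_scene_rejected(self):
        with pytest.raises(ValueError):
            scene_bias_deviations(estimate_set([1, 2], [1, 2]))


class TestVarianceByDuration:
    def test_identical_estimates_have_zero_sd(self):
        est = estimate_set([1, 1, 4, 4], [2, 2, 5, 5])
        out = variance_by_duration(est)
        assert (out["per_duration"]["sd"] == 0).all()

    def test_recovers_known_coefficient_of_variation(self):
        """Estimates duration*(1+e), e ~ N(0, 0.1^2): SD-vs-mean slope ~ 0.1."""
        r = np.random.default_rng(2024)
        true, pred = [], []
        for d in STANDARD_DURATIONS_S:
            e = r.normal(0.0, 0.1, size=200)
            true.extend([d] * 200)
            pred.extend(d * (1.0 + e))
        out = variance_by_duration(estimate_set(true, pred))
        assert out["sd_vs_mean_slope"] == pytest.approx(
            0.1, abs=3 * out["sd_vs_mean_stderr"]
        )

    def test_doubling_estimates_doubles_every_sd(self, rng):
        true = np.repeat([1.0, 4.0, 8.0], 5)
        pred = true * rng.uniform(0.8, 1.2, size=len(true))
        sd1 = variance_by_duration(estimate_set(true, pred))["per_duration"]["sd"]
        sd2 = variance_by_duration(estimate_set(true, 2 * pred))["per_duration"]["sd"]
        np.testing.assert_allclose(sd2, 2 * sd1, rtol=1e-12)

    def test_single_trial_durations_omitted(self):
        est = estimate_set([1, 1, 4, 4, 8], [1, 2, 4, 5, 8])
        out = variance_by_duration(est)
        assert out["per_duration"]["true_s"].tolist() == [1.0, 4.0]


def test_negative_predictions_kept_raw_and_clamped():
    est = estimate_set([1.0, 2.0], [-0.5, 2.5])
    assert est.frame["predicted_s"].tolist() == [-0.5, 2.5]
    assert est.frame["predicted_clamped_s"].tolist() == [0.0, 2.5]
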