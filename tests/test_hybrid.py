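"""Threshold routing, evaluation metrics, and model comparison."""

import numpy as np
import pytest

import enoseflow as ef
from enoseflow.gabp import GABPModel, decode, predict_gabp
from enoseflow.hybrid import (
    HybridModel,
    compare_models,
    compute_threshold,
    evaluate,
    flow_blind_baseline,
    predict_hybrid,
)
from enoseflow.mr import QUADRATIC_TERMS, predict_mr

from conftest import make_samples


def constant_run(concentration, flow, value, n=200, split="train"):
    cond = ef.Condition(concentration, flow, 1, split)
    return ef.RunSeries(cond, 10.0, n / 10.0, np.full(n, value), np.full(n, flow))


def dummy_mr(coef=(10.0, 100.0, 0.0, 0.0, 0.0)):
    return ef.MRModel(form="quadratic", terms=QUADRATIC_TERMS, coef=list(coef))


def dummy_gabp(seed=0):
    return GABPModel(
        net=decode(np.random.default_rng(seed).uniform(-1, 1, 9)),
        x_min=np.zeros(2),
        x_range=np.ones(2),
        y_min=0.0,
        y_range=200.0,
    )


class TestComputeThreshold:
    def test_constant_run_gives_its_value(self):
        runs = [constant_run(50.0, 1000.0, 0.42)]
        assert compute_threshold(runs) == pytest.approx(0.42)

    def test_two_replicates_average(self):
        r1 = constant_run(50.0, 1000.0, 0.40)
        r2 = ef.RunSeries(ef.Condition(50.0, 1000.0, 2, "train"), 10.0, 20.0, np.full(200, 0.50), np.full(200, 1000.0))
        assert compute_threshold([r1, r2]) == pytest.approx(0.45)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing condition"):
            compute_threshold([constant_run(25.0, 1000.0, 0.4)])

    def test_threshold_sits_between_neighbour_concentrations(self, default_result):
        """The 50 ppb / 1000 SCCM mean response separates the 35 and
        100 ppb responses at the same flow (generator monotonicity)."""
        tau = default_result.threshold_volts
        train = [r for r in default_result.runs if r.condition.split == "train"]

        def mean_at(c):
            run = next(r for r in train if r.condition.concentration_ppb == c and r.condition.flow_sccm == 1000.0)
            return float(np.mean(ef.moving_average(run.no_voltage, 51)))

        assert mean_at(35.0) < tau < mean_at(100.0)


class TestRouting:
    def test_below_threshold_routes_to_mr(self):
        model = HybridModel(dummy_mr(), dummy_gabp(), threshold_volts=0.5)
        x1, x2 = 0.3, 0.6
        assert predict_hybrid(model, x1, x2) == predict_mr(model.mr, x1, x2)

    def test_above_threshold_routes_to_gabp(self):
        model = HybridModel(dummy_mr(), dummy_gabp(), threshold_volts=0.5)
        x1, x2 = 0.8, 0.6
        assert predict_hybrid(model, x1, x2) == predict_gabp(model.gabp, x1, x2)

    def test_tie_routes_to_gabp(self):
        model = HybridModel(dummy_mr(), dummy_gabp(), threshold_volts=0.5)
        assert predict_hybrid(model, 0.5, 0.6) == predict_gabp(model.gabp, 0.5, 0.6)

    def test_every_prediction_identical_to_one_submodel(self, default_result):
        """Routing exactness on the full test set of the default study."""
        model = default_result.hybrid_model
        for s in default_result.test_samples[::7]:
            pred = predict_hybrid(model, s.x1, s.x2)
            assert pred == predict_mr(model.mr, s.x1, s.x2) or pred == predict_gabp(model.gabp, s.x1, s.x2)

    def test_json_round_trip(self, tmp_path):
        model = HybridModel(dummy_mr(), dummy_gabp(), threshold_volts=0.47)
        path = tmp_path / "hybrid.json"
        model.to_json(path)
        back = HybridModel.from_json(path)
        assert back.threshold_volts == 0.47
        assert predict_hybrid(back, 0.8, 0.5) == pytest.approx(predict_hybrid(model, 0.8, 0.5))


class TestEvaluate:
    def test_perfect_predictions(self):
        truths = np.array([5.0, 50.0, 200.0])
        m = evaluate(truths, truths)
        assert (m.r2, m.rmse, m.precision_fs) == (1.0, 0.0, 0.0)

    def test_headline_precision_arithmetic(self):
        """A single worst error of 13.72 ppb on a 200 ppb full scale is
        6.86 %FS."""
        truths = np.array([50.0, 100.0])
        preds = np.array([50.0, 113.72])
        assert evaluate(preds, truths).precision_fs == pytest.approx(6.86)

    def test_rmse_hand_arithmetic(self):
        m = evaluate(np.array([8.0, 14.0]), np.array([5.0, 10.0]))
        assert m.rmse == pytest.approx(np.sqrt(12.5))
        assert m.mse == pytest.approx(12.5)

    def test_precision_permutation_invariant_and_scales_with_fs(self):
        rng = np.random.default_rng(0)
        truths = rng.uniform(5, 200, 30)
        preds = truths + rng.normal(0, 3, 30)
        m1 = evaluate(preds, truths)
        perm = rng.permutation(30)
        m2 = evaluate(preds[perm], truths[perm])
        assert m1.precision_fs == pytest.approx(m2.precision_fs)
        m_half = evaluate(preds, truths, full_scale_ppb=100.0)
        assert m_half.precision_fs == pytest.approx(2 * m1.precision_fs)

    def test_mean_error_variant(self):
        truths = np.array([10.0, 20.0])
        preds = np.array([12.0, 26.0])
        assert evaluate(preds, truths, error_stat="mean").precision_fs == pytest.approx(4.0 / 200 * 100)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="zero variance"):
            evaluate([1.0, 2.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0], full_scale_ppb=0.0)


class TestCompareModels:
    @staticmethod
    def samples():
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0.2, 1.0, 30)
        x2 = rng.uniform(0.2, 1.2, 30)
        y = rng.uniform(5, 200, 30)
        return make_samples(x1, x2, y)

    def test_threshold_above_all_makes_hybrid_equal_mr(self):
        mr, gabp = dummy_mr(), dummy_gabp()
        samples = self.samples()
        hybrid = HybridModel(mr, gabp, threshold_volts=10.0)
        cmp = compare_models(mr, gabp, hybrid, samples)
        assert cmp.metrics["hybrid"].rmse == pytest.approx(cmp.metrics["mr"].rmse)
        assert cmp.hybrid_no_worse_than_mr

    def test_threshold_below_all_makes_hybrid_equal_gabp(self):
        mr, gabp = dummy_mr(), dummy_gabp()
        samples = self.samples()
        hybrid = HybridModel(mr, gabp, threshold_volts=-10.0)
        cmp = compare_models(mr, gabp, hybrid, samples)
        assert cmp.metrics["hybrid"].rmse == pytest.approx(cmp.metrics["gabp"].rmse)
        assert cmp.hybrid_no_worse_than_gabp

    def test_rmse_breakdown_covers_all_concentrations(self, default_result):
        table = default_result.comparison.rmse_by_concentration
        assert sorted(table["concentration_ppb"]) == [5, 25, 35, 50, 100, 200]
        assert {"rmse_mr", "rmse_gabp", "rmse_hybrid"} <= set(table.columns)

    def test_empty_test_set_rejected(self):
        mr, gabp = dummy_mr(), dummy_gabp()
        with pytest.raises(ValueError):
            compare_models(mr, gabp, HybridModel(mr, gabp, 0.5), [])


class TestBaseline:
    def test_fitted_only_at_peak_flow_and_ignores_flow(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0.2, 1.0, 40)
        y = 250 * (x1 - 0.2)
        at_peak = make_samples(x1[:20], np.full(20, 1.0), y[:20])
        off_peak = [
            ef.CalibrationSample(x1=float(a), x2=0.2, y=float(c), feature_kind="mean",
                                 condition=ef.Condition(50.0, 200.0, 1))
            for a, c in zip(x1[20:], y[20:])
        ]
        baseline = flow_blind_baseline(at_peak + off_peak, peak_flow_sccm=1000.0)
        assert baseline.slope == pytest.approx(250.0, rel=1e-6)
        # flow-blind: x2 plays no role in prediction
        assert baseline.predict(0.5) == pytest.approx(baseline.predict(0.5, 0.9))

    def test_missing_peak_flow_rejected(self):
        samples = make_samples([0.3, 0.4], [0.2, 0.2], [5.0, 25.0])  # flow 1000 in condition
        with pytest.raises(ValueError):
            flow_blind_baseline(samples, peak_flow_sccm=800.0)
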