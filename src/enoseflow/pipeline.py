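"""End-to-end orchestration: simulate -> preprocess -> ANOVA -> calibrate
-> hybrid -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import AnovaResult, FactorialTable, LsdResult, lsd_subsets, normality_test, two_way_anova, variance_homogeneity_test
from .config import ExperimentConfig
from .gabp import GABPModel, train_gabp
from .hybrid import (
    HybridModel,
    LinearBaseline,
    Metrics,
    ModelComparison,
    compare_models,
    compute_threshold,
    evaluate,
    flow_blind_baseline,
)
from .mr import MRModel, comparison_table, fit_mr, model_select
from .preprocess import CalibrationSample, build_calibration_samples, samples_to_frame
from .runio import write_dataset, write_features
from .simulate import RunSeries, generate_design, simulate_dataset

__all__ = ["ExperimentResult", "run_pipeline", "write_report"]


@dataclass
class ExperimentResult:
    """Everything one experiment produced, in memory."""

    config: ExperimentConfig
    runs: list[RunSeries]
    train_samples: list[CalibrationSample]
    test_samples: list[CalibrationSample]
    anova: AnovaResult
    lsd_flow: LsdResult
    levene: tuple[float, float]
    shapiro: tuple[float, float]
    mr_candidates: list[MRModel]
    mr_model: MRModel
    gabp_model: GABPModel
    threshold_volts: float
    hybrid_model: HybridModel
    baseline: LinearBaseline
    baseline_metrics: Metrics
    comparison: ModelComparison

    def summary(self) -> pd.DataFrame:
        frame = self.comparison.summary()
        base = {"model": "flow_blind_baseline", **self.baseline_metrics.to_dict()}
        return pd.concat([frame, pd.DataFrame([base])], ignore_index=True)


def _stage(name: str):
    def wrap(fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    return wrap


def run_pipeline(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the whole flow-correction experiment from a config.

    Fully reproducible: the result is a pure function of the config
    (including its seeds).
    """
    cfg = config if config is not None else ExperimentConfig()

    design = _stage("design")(lambda: generate_design(cfg.concentrations_ppb, cfg.flows_sccm, cfg.replicates))
    runs = _stage("simulate")(lambda: simulate_dataset(design, cfg.sim, cfg.sample_rate_hz, cfg.duration_s))
    train_runs = [r for r in runs if r.condition.split == "train"]
    test_runs = [r for r in runs if r.condition.split == "test"]

    train_samples = _stage("preprocess")(
        lambda: build_calibration_samples(train_runs, cfg.window, cfg.span, cfg.flow_divisor)
    )
    test_samples = _stage("preprocess")(
        lambda: build_calibration_samples(test_runs, cfg.window, cfg.span, cfg.flow_divisor)
    )

    def do_anova():
        table = FactorialTable.from_samples(train_samples)
        result = two_way_anova(table)
        lsd = lsd_subsets(table, factor="a", alpha=cfg.alpha)
        groups = [table.responses[i].ravel() for i in range(table.shape[0])]
        levene = variance_homogeneity_test(groups)
        residuals = (table.responses - table.responses.mean(axis=2, keepdims=True)).ravel()
        shapiro = normality_test(residuals)
        return result, lsd, levene, shapiro

    anova_result, lsd_flow, levene, shapiro = _stage("anova")(do_anova)

    def do_mr():
        cands = [fit_mr(train_samples, form="linear", x2_divisor=cfg.flow_divisor),
                 fit_mr(train_samples, form=cfg.mr_form, x2_divisor=cfg.flow_divisor)]
        return cands, model_select(cands, cfg.alpha)

    mr_candidates, mr_model = _stage("fit-mr")(do_mr)

    gabp_model = _stage("fit-gabp")(
        lambda: train_gabp(
            train_samples, cfg.ga,
            learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
            tolerance=cfg.tolerance, seed=cfg.seed,
        )
    )

    threshold = _stage("threshold")(
        lambda: compute_threshold(train_runs, cfg.window, cfg.threshold_concentration_ppb, cfg.threshold_flow_sccm)
    )
    hybrid_model = HybridModel(
        mr=mr_model,
        gabp=gabp_model,
        threshold_volts=threshold,
        provenance={
            "concentration_ppb": cfg.threshold_concentration_ppb,
            "flow_sccm": cfg.threshold_flow_sccm,
            "statistic": "mean",
        },
    )

    def do_eval():
        comparison = compare_models(mr_model, gabp_model, hybrid_model, test_samples, cfg.full_scale_ppb)
        baseline = flow_blind_baseline(train_samples, cfg.threshold_flow_sccm)
        x1 = np.array([s.x1 for s in test_samples])
        y = np.array([s.y for s in test_samples])
        baseline_metrics = evaluate(baseline.predict(x1), y, cfg.full_scale_ppb)
        return comparison, baseline, baseline_metrics

    comparison, baseline, baseline_metrics = _stage("evaluate")(do_eval)

    return ExperimentResult(
        config=cfg,
        runs=runs,
        train_samples=train_samples,
        test_samples=test_samples,
        anova=anova_result,
        lsd_flow=lsd_flow,
        levene=levene,
        shapiro=shapiro,
        mr_candidates=mr_candidates,
        mr_model=mr_model,
        gabp_model=gabp_model,
        threshold_volts=threshold,
        hybrid_model=hybrid_model,
        baseline=baseline,
        baseline_metrics=baseline_metrics,
        comparison=comparison,
    )


def write_report(result: ExperimentResult, out_dir) -> Path:
    """Persist models, tables and metrics for one experiment."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_file(out_dir / "config.yaml")
    write_dataset(result.runs, out_dir / "runs")
    write_features(result.train_samples, out_dir / "features_train.csv")
    write_features(result.test_samples, out_dir / "features_test.csv")
    result.anova.to_frame().to_csv(out_dir / "anova.csv", index=False)
    result.lsd_flow.to_frame().to_csv(out_dir / "lsd_flow.csv", index=False)
    result.mr_model.to_json(out_dir / "model_mr.json")
    comparison_table(result.mr_candidates, result.config.alpha).to_csv(out_dir / "mr_comparison.csv", index=False)
    result.gabp_model.to_json(out_dir / "model_gabp.json")
    result.hybrid_model.to_json(out_dir / "model_hybrid.json")
    result.summary().to_csv(out_dir / "metrics.csv", index=False)
    result.comparison.rmse_by_concentration.to_csv(out_dir / "rmse_by_concentration.csv", index=False)
    return out_dir
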