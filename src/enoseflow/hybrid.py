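"""Threshold-routed hybrid calibrator and model evaluation metrics.

The hybrid combines the two calibrators by discriminating on the raw
NO-sensor eigenvalue x1: the polynomial (MR) model is more accurate at
low concentrations, the GA-BP network at high concentrations, so each
sample is routed by comparing x1 to a threshold tau — the mean smoothed
NO-sensor response recorded at 50 ppb and 1000 SCCM in the training set.
Samples with x1 below tau go to MR, at or above tau to GA-BP (the tie is
a measure-zero event; it routes to GA-BP).

Metrics follow instrument practice: R^2, MSE, RMSE on the concentration
scale (ppb), and precision as a percentage of full scale,
max |error| / FS * 100 with FS = 200 ppb by default (a mean-absolute
variant is available via ``error_stat``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gabp import GABPModel, predict_gabp
from .mr import MRModel, predict_mr
from .preprocess import CalibrationSample, extract_features, moving_average
from .simulate import RunSeries

__all__ = [
    "Metrics",
    "HybridModel",
    "LinearBaseline",
    "compute_threshold",
    "predict_hybrid",
    "evaluate",
    "compare_models",
    "flow_blind_baseline",
]


def compute_threshold(
    runs: Iterable[RunSeries],
    window: int = 51,
    concentration_ppb: float = 50.0,
    flow_sccm: float = 1000.0,
) -> float:
    """Mean smoothed NO-channel response over the training run(s) recorded
    at the discrimination condition (50 ppb, 1000 SCCM by default)."""
    matching = [
        r for r in runs
        if np.isclose(r.condition.concentration_ppb, concentration_ppb)
        and np.isclose(r.condition.flow_sccm, flow_sccm)
    ]
    if not matching:
        raise ValueError(
            f"missing condition: no run at {concentration_ppb} ppb / {flow_sccm} SCCM in the training set"
        )
    run_means = [float(np.mean(moving_average(r.no_voltage, window))) for r in matching]
    return float(np.mean(run_means))


@dataclass
class HybridModel:
    """MR + GA-BP pair with the routing threshold tau (volts)."""

    mr: MRModel
    gabp: GABPModel
    threshold_volts: float
    provenance: dict = field(
        default_factory=lambda: {"concentration_ppb": 50.0, "flow_sccm": 1000.0, "statistic": "mean"}
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_volts):
            raise ValueError("threshold must be finite")

    def predict(self, x1, x2):
        return predict_hybrid(self, x1, x2)

    def to_dict(self) -> dict:
        return {
            "kind": "hybrid",
            "threshold_volts": self.threshold_volts,
            "provenance": self.provenance,
            "mr": self.mr.to_dict(),
            "gabp": self.gabp.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HybridModel":
        return cls(
            mr=MRModel.from_dict(data["mr"]),
            gabp=GABPModel.from_dict(data["gabp"]),
            threshold_volts=float(data["threshold_volts"]),
            provenance=dict(data.get("provenance", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HybridModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_hybrid(model: HybridModel, x1, x2):
    """Route each sample to exactly one sub-model by its x1 value.

    The returned prediction is bit-identical to the routed sub-model's
    own prediction.
    """
    x1a = np.atleast_1d(np.asarray(x1, dtype=float))
    x2a = np.atleast_1d(np.asarray(x2, dtype=float))
    out = np.empty_like(x1a)
    use_gabp = x1a >= model.threshold_volts
    if use_gabp.any():
        out[use_gabp] = np.atleast_1d(predict_gabp(model.gabp, x1a[use_gabp], x2a[use_gabp]))
    if (~use_gabp).any():
        out[~use_gabp] = np.atleast_1d(predict_mr(model.mr, x1a[~use_gabp], x2a[~use_gabp]))
    return float(out[0]) if np.isscalar(x1) or np.asarray(x1).ndim == 0 else out


@dataclass
class Metrics:
    """Goodness-of-fit and instrument-precision summary."""

    r2: float
    mse: float
    rmse: float
    precision_fs: float
    full_scale_ppb: float
    per_concentration: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mse": self.mse,
            "rmse": self.rmse,
            "precision_fs": self.precision_fs,
            "full_scale_ppb": self.full_scale_ppb,
        }


def evaluate(
    predictions,
    truths,
    full_scale_ppb: float = 200.0,
    error_stat: str = "max",
) -> Metrics:
    """Score predictions against true concentrations.

    ``precision_fs`` is ``max |error| / full_scale * 100`` (or the
    mean-absolute variant with ``error_stat="mean"``).  R^2 requires the
    truths to vary.
    """
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    if full_scale_ppb <= 0:
        raise ValueError("full_scale_ppb must be > 0")
    if error_stat not in ("max", "mean"):
        raise ValueError("error_stat must be 'max' or 'mean'")
    err = pred - truth
    sstot = float(np.sum((truth - truth.mean()) ** 2))
    if sstot == 0:
        raise ValueError("R^2 undefined: truths have zero variance")
    sse = float(np.sum(err**2))
    mse = sse / truth.size
    stat = np.max(np.abs(err)) if error_stat == "max" else np.mean(np.abs(err))
    per_conc = (
        pd.DataFrame({"concentration_ppb": truth, "prediction": pred})
        .groupby("concentration_ppb", as_index=False)
        .agg(mean_prediction=("prediction", "mean"), n=("prediction", "size"))
    )
    return Metrics(
        r2=1.0 - sse / sstot,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        precision_fs=float(stat / full_scale_ppb * 100.0),
        full_scale_ppb=float(full_scale_ppb),
        per_concentration=per_conc,
    )


@dataclass
class LinearBaseline:
    """Flow-blind one-line calibration: y = slope * x1 + intercept, fitted
    only at the peak-gain flow and applied at every flow.  Emulates an
    uncorrected instrument that ignores the pump flow entirely."""

    slope: float
    intercept: float
    fitted_at_flow_sccm: float

    def predict(self, x1, x2=None):
        x1a = np.asarray(x1, dtype=float)
        return self.slope * x1a + self.intercept


def flow_blind_baseline(
    train_samples: Sequence[CalibrationSample],
    peak_flow_sccm: float = 1000.0,
) -> LinearBaseline:
    """Fit the uncorrected baseline on the training samples recorded at the
    peak-gain flow."""
    sub = [s for s in train_samples if np.isclose(s.condition.flow_sccm, peak_flow_sccm)]
    if len(sub) < 2:
        raise ValueError(f"missing condition: need >= 2 training samples at {peak_flow_sccm} SCCM")
    x1 = np.array([s.x1 for s in sub])
    y = np.array([s.y for s in sub])
    slope, intercept = np.polyfit(x1, y, 1)
    return LinearBaseline(float(slope), float(intercept), float(peak_flow_sccm))


@dataclass
class ModelComparison:
    """Side-by-side metrics for the three calibrators on a shared test set."""

    metrics: dict[str, Metrics]
    rmse_by_concentration: pd.DataFrame
    hybrid_no_worse_than_mr: bool
    hybrid_no_worse_than_gabp: bool

    def summary(self) -> pd.DataFrame:
        rows = [{"model": name, **m.to_dict()} for name, m in self.metrics.items()]
        return pd.DataFrame(rows)


def compare_models(
    mr: MRModel,
    gabp: GABPModel,
    hybrid: HybridModel,
    samples: Sequence[CalibrationSample],
    full_scale_ppb: float = 200.0,
) -> ModelComparison:
    """Evaluate MR, GA-BP and the hybrid on the same test samples, with an
    RMSE-by-concentration breakdown."""
    samples = list(samples)
    if not samples:
        raise ValueError("test sample set must be non-empty")
    x1 = np.array([s.x1 for s in samples])
    x2 = np.array([s.x2 for s in samples])
    y = np.array([s.y for s in samples])
    preds = {
        "mr": np.atleast_1d(predict_mr(mr, x1, x2)),
        "gabp": np.atleast_1d(predict_gabp(gabp, x1, x2)),
        "hybrid": np.atleast_1d(predict_hybrid(hybrid, x1, x2)),
    }
    metrics = {name: evaluate(p, y, full_scale_ppb) for name, p in preds.items()}

    rows = []
    for conc in np.unique(y):
        mask = y == conc
        row = {"concentration_ppb": float(conc)}
        for name, p in preds.items():
            row[f"rmse_{name}"] = float(np.sqrt(np.mean((p[mask] - y[mask]) ** 2)))
        rows.append(row)
    breakdown = pd.DataFrame(rows)

    return ModelComparison(
        metrics=metrics,
        rmse_by_concentration=breakdown,
        hybrid_no_worse_than_mr=metrics["hybrid"].rmse <= metrics["mr"].rmse,
        hybrid_no_worse_than_gabp=metrics["hybrid"].rmse <= metrics["gabp"].rmse,
    )
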