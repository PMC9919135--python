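"""Channel smoothing and eigenvalue feature extraction.

The NO channel is smoothed with a centered moving average and the flow
channel with a loess (locally weighted linear regression) filter.  Each
smoothed channel is reduced to five summary statistics — maximum, mean,
median, first quartile (Q1), third quartile (Q3) — called "eigenvalues" in
the e-nose literature.  Pairing the NO and flow eigenvalues of the same
kind yields five calibration samples per run, each labelled with the run's
true concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import Condition, RunSeries

__all__ = [
    "FEATURE_KINDS",
    "FeatureVector",
    "CalibrationSample",
    "moving_average",
    "loess_smooth",
    "extract_features",
    "build_calibration_samples",
    "samples_to_frame",
    "frame_to_samples",
]

#: Canonical order of the five eigenvalue kinds.
FEATURE_KINDS: tuple[str, ...] = ("maximum", "mean", "median", "q1", "q3")


@dataclass(frozen=True)
class FeatureVector:
    """The five eigenvalues of one smoothed channel, in the channel's units."""

    maximum: float
    mean: float
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        vals = (self.maximum, self.mean, self.median, self.q1, self.q3)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("feature values must all be finite")
        tol = 1e-9 * max(1.0, *(abs(v) for v in vals))
        if not (self.q1 <= self.median + tol and self.median <= self.q3 + tol and self.q3 <= self.maximum + tol):
            raise ValueError("feature ordering q1 <= median <= q3 <= maximum violated")

    def by_kind(self, kind: str) -> float:
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        return float(getattr(self, kind))


@dataclass(frozen=True)
class CalibrationSample:
    """One (x1, x2, y) triple fed to the calibration models.

    ``x1`` is a NO-channel eigenvalue in volts, ``x2`` the flow-channel
    eigenvalue of the same kind after division by the flow divisor
    (1000 by default, i.e. SCCM -> SLPM so x2 is order 1), and ``y`` the
    true concentration in ppb.
    """

    x1: float
    x2: float
    y: float
    feature_kind: str
    condition: Condition

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if not (np.isfinite(self.x1) and np.isfinite(self.x2) and np.isfinite(self.y)):
            raise ValueError("sample values must be finite")
        if self.y <= 0:
            raise ValueError("true concentration y must be > 0")


def moving_average(series, window: int = 51) -> np.ndarray:
    """Centered moving average with shrunken symmetric windows at the edges.

    ``window`` must be odd and no longer than the series.  Output has the
    same length as the input; at index ``i`` the effective half-width is
    ``min(window // 2, i, n - 1 - i)`` so the window stays symmetric.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    n = y.size
    if window < 1 or window % 2 == 0 or window > n:
        raise ValueError(f"window must be odd and in [1, {n}], got {window}")
    half = window // 2
    idx = np.arange(n)
    radius = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(y)))
    return (csum[idx + radius + 1] - csum[idx - radius]) / (2 * radius + 1)


def loess_smooth(series, span: float = 0.3, weights: str = "tricube") -> np.ndarray:
    """Loess smoothing: locally weighted linear regression on the index.

    At each index the nearest ``ceil(span * n)`` points (a contiguous
    window) are fitted with a degree-1 polynomial under tricube distance
    weights and the fit is evaluated at that index.  ``weights="uniform"``
    disables the distance weighting, in which case ``span=1`` reduces to
    the global least-squares line.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    n = y.size
    if not 0 < span <= 1:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    k = int(np.ceil(span * n))
    if k < 2:
        raise ValueError(f"span too small: span * length = {span * n:.3g} < 2")
    if weights not in ("tricube", "uniform"):
        raise ValueError(f"weights must be 'tricube' or 'uniform', got {weights!r}")

    idx = np.arange(n)
    start = np.clip(idx - (k - 1) // 2, 0, n - k)
    win = start[:, None] + np.arange(k)[None, :]          # (n, k) window indices
    x = win.astype(float)
    yy = y[win]
    d = np.abs(x - idx[:, None])
    if weights == "tricube":
        dmax = d.max(axis=1, keepdims=True)
        dmax = np.where(dmax == 0, 1.0, dmax)
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
    else:
        w = np.ones_like(d)

    # Weighted linear fit per row, centered on the evaluation index so the
    # intercept is directly the fitted value there.
    xc = x - idx[:, None]
    sw = w.sum(axis=1)
    swx = (w * xc).sum(axis=1)
    swy = (w * yy).sum(axis=1)
    swxx = (w * xc * xc).sum(axis=1)
    swxy = (w * xc * yy).sum(axis=1)
    denom = sw * swxx - swx**2
    safe = np.abs(denom) > 1e-12 * np.maximum(sw * swxx, 1e-300)
    slope = np.where(safe, (sw * swxy - swx * swy) / np.where(safe, denom, 1.0), 0.0)
    return (swy - slope * swx) / sw


def extract_features(series) -> FeatureVector:
    """Reduce a (smoothed) channel to its five eigenvalues.

    Quartiles use linear interpolation between closest order statistics
    (numpy's default, the "type 7" convention).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("cannot extract features from an empty series")
    q1, med, q3 = np.percentile(y, [25.0, 50.0, 75.0])
    return FeatureVector(
        maximum=float(np.max(y)),
        mean=float(np.mean(y)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def build_calibration_samples(
    runs: Iterable[RunSeries],
    window: int = 51,
    span: float = 0.3,
    flow_divisor: float = 1000.0,
) -> list[CalibrationSample]:
    """Smooth both channels of every run and emit 5 samples per run.

    The NO channel is moving-average smoothed (default 51 samples, ~5 s at
    10 Hz) and the flow channel loess smoothed (default span 0.3).  The
    eigenvalues of the two channels are paired by kind — maximum with
    maximum, mean with mean, and so on.
    """
    samples: list[CalibrationSample] = []
    for run in runs:
        if run.no_voltage.size == 0 or run.flow_sccm.size == 0:
            raise ValueError("malformed run: both channels must be non-empty")
        no_feat = extract_features(moving_average(run.no_voltage, window))
        flow_feat = extract_features(loess_smooth(run.flow_sccm, span))
        for kind in FEATURE_KINDS:
            samples.append(
                CalibrationSample(
                    x1=no_feat.by_kind(kind),
                    x2=flow_feat.by_kind(kind) / flow_divisor,
                    y=run.condition.concentration_ppb,
                    feature_kind=kind,
                    condition=run.condition,
                )
            )
    return samples


def samples_to_frame(samples: Sequence[CalibrationSample]) -> pd.DataFrame:
    """Tabulate calibration samples (one row per sample)."""
    return pd.DataFrame(
        {
            "concentration_ppb": [s.condition.concentration_ppb for s in samples],
            "flow_set_sccm": [s.condition.flow_sccm for s in samples],
            "replicate": [s.condition.replicate for s in samples],
            "split": [s.condition.split for s in samples],
            "feature_kind": [s.feature_kind for s in samples],
            "x1_volts": [s.x1 for s in samples],
            "x2_scaled": [s.x2 for s in samples],
        }
    )


def frame_to_samples(frame: pd.DataFrame) -> list[CalibrationSample]:
    """Inverse of :func:`samples_to_frame`."""
    required = {"concentration_ppb", "flow_set_sccm", "replicate", "split", "feature_kind", "x1_volts", "x2_scaled"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    samples = []
    for row in frame.itertuples(index=False):
        cond = Condition(
            float(row.concentration_ppb), float(row.flow_set_sccm), int(row.replicate), str(row.split)
        )
        samples.append(
            CalibrationSample(
                x1=float(row.x1_volts),
                x2=float(row.x2_scaled),
                y=float(row.concentration_ppb),
                feature_kind=str(row.feature_kind),
                condition=cond,
            )
        )
    return samples
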