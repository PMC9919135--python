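"""Synthetic bench-experiment generator for the active-pumping e-nose.

The bench protocol this emulates: a factorial sweep over sampling-gas NO
concentration (ppb) and pump suction flow (SCCM), two replicates per cell,
each run recording the NO-sensor voltage and the flow-sensor reading at
10 Hz for 5 minutes.  The NO channel rises exponentially to an equilibrium
plateau whose level grows with concentration and depends unimodally on the
pump flow (sensor response peaks near 1000 SCCM, where turbulence over the
electrochemical surface is strongest, and is weakest at 200 SCCM).

Nothing here is fitted to data; the generator is a parametric stand-in for
the bench rig so the whole correction pipeline can be exercised end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CONCENTRATIONS_PPB",
    "DEFAULT_FLOWS_SCCM",
    "Condition",
    "RunSeries",
    "SimParams",
    "generate_design",
    "flow_gain",
    "simulate_run",
    "simulate_dataset",
]

#: Design levels of the default factorial sweep.
DEFAULT_CONCENTRATIONS_PPB: tuple[float, ...] = (5.0, 25.0, 35.0, 50.0, 100.0, 200.0)
DEFAULT_FLOWS_SCCM: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0)


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design.

    Parameters
    ----------
    concentration_ppb
        True NO concentration of the sampling gas.  Zero is allowed so a
        blank (carrier-only) run can be simulated; the design generator
        itself only produces strictly positive levels.
    flow_sccm
        Pump suction flow capacity set point.
    replicate
        1-based replicate index within the cell.
    split
        Either ``"train"`` or ``"test"``.
    """

    concentration_ppb: float
    flow_sccm: float
    replicate: int
    split: str = "train"

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration_ppb) or self.concentration_ppb < 0:
            raise ValueError(f"concentration_ppb must be finite and >= 0, got {self.concentration_ppb}")
        if not np.isfinite(self.flow_sccm) or self.flow_sccm <= 0:
            raise ValueError(f"flow_sccm must be finite and > 0, got {self.flow_sccm}")
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")

    @property
    def key(self) -> tuple[float, float, int]:
        """The identifying (concentration, flow, replicate) triple."""
        return (float(self.concentration_ppb), float(self.flow_sccm), int(self.replicate))


@dataclass
class RunSeries:
    """One recorded run: two synchronized channels plus its condition.

    ``no_voltage`` is the NO-sensor output in volts and ``flow_sccm`` the
    flow-sensor reading; both have exactly ``round(sample_rate_hz *
    duration_s)`` samples.
    """

    condition: Condition
    sample_rate_hz: float
    duration_s: float
    no_voltage: np.ndarray
    flow_sccm: np.ndarray

    def __post_init__(self) -> None:
        self.no_voltage = np.asarray(self.no_voltage, dtype=float)
        self.flow_sccm = np.asarray(self.flow_sccm, dtype=float)
        n = int(round(self.sample_rate_hz * self.duration_s))
        if self.no_voltage.shape != (n,) or self.flow_sccm.shape != (n,):
            raise ValueError(
                f"channels must both have length {n} "
                f"(= round({self.sample_rate_hz} Hz x {self.duration_s} s)); "
                f"got {self.no_voltage.shape} and {self.flow_sccm.shape}"
            )
        if not (np.all(np.isfinite(self.no_voltage)) and np.all(np.isfinite(self.flow_sccm))):
            raise ValueError("channel values must all be finite")

    @property
    def n_samples(self) -> int:
        return self.no_voltage.size

    @property
    def time_s(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class SimParams:
    """Parameters of the synthetic sensor-response model.

    The noiseless NO channel is

    ``baseline_voltage + sensitivity * S(c / full_scale_ppb) * g(flow)
    * (1 - exp(-t / rise_time_constant))``

    where ``g`` is the unimodal flow-gain curve (see :func:`flow_gain`),
    normalized to 1 at its peak, and ``S`` a top-of-range saturating
    dose-response ``S(u) = (u - a u^3) / (1 - a)`` with
    ``a = saturation_strength`` (``S(0) = 0``, ``S(1) = 1``): the sensor
    is essentially linear over the lower half of its range and loses
    incremental sensitivity toward full scale (per-ppb response at full
    scale is ``(1 - 3a)/(1 - a)`` of its low-end value).  The flow
    channel is the set flow plus noise.  Gaussian i.i.d. noise is added
    per sample on both channels.

    Defaults: baseline 0.2 V; sensitivity 0.8 V at full scale and peak
    gain; saturation strength 0.12 (per-ppb sensitivity at full scale is
    ~73% of its low-range value); rise time constant 12 s (equilibrium
    well inside the 5-minute
    run; the rise phase leaves a small spread between the run's summary
    features); flow gain peaking at 1000 SCCM with a ~15% loss at
    200 SCCM and a ~7% loss at 1200 SCCM; per-sample sensor noise 10 mV
    (~2% of a mid-scale response) plus run-to-run gain jitter of 1.5% and
    baseline jitter of 5 mV, so smoothed run means repeat with a CV of
    about 1-2%; flow noise 5 SCCM.
    """

    baseline_voltage: float = 0.2
    sensitivity: float = 0.8
    saturation_strength: float = 0.12
    rise_time_constant: float = 12.0
    peak_flow_sccm: float = 1000.0
    flow_gain_spread: float = 1.0
    noise_sd_voltage: float = 0.01
    run_gain_jitter: float = 0.015
    run_baseline_jitter_voltage: float = 0.005
    flow_noise_sd: float = 5.0
    full_scale_ppb: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_voltage < 0 or self.flow_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.run_gain_jitter < 0 or self.run_baseline_jitter_voltage < 0:
            raise ValueError("run-level jitter parameters must be >= 0")
        if self.peak_flow_sccm <= 0:
            raise ValueError("peak_flow_sccm must be > 0")
        if not 0 < self.flow_gain_spread <= 4.0:
            raise ValueError("flow_gain_spread must lie in (0, 4]")
        if self.rise_time_constant <= 0:
            raise ValueError("rise_time_constant must be > 0")
        if not 0 <= self.saturation_strength <= 0.3:
            raise ValueError("saturation_strength must lie in [0, 0.3]")
        if self.full_scale_ppb <= 0:
            raise ValueError("full_scale_ppb must be > 0")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


def generate_design(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_PPB,
    flows: Sequence[float] = DEFAULT_FLOWS_SCCM,
    replicates: int = 2,
) -> list[Condition]:
    """Build the full factorial design.

    Returns ``len(concentrations) * len(flows) * replicates`` conditions.
    Replicate 1 is labelled ``train`` and every later replicate ``test``,
    mirroring a bench campaign where one sweep calibrates the instrument
    and the second validates it.
    """
    if len(concentrations) == 0 or len(flows) == 0 or replicates < 1:
        raise ValueError("invalid design: need >= 1 concentration, flow, and replicate")
    if any(c <= 0 for c in concentrations):
        raise ValueError("invalid design: concentrations must be > 0")
    if any(f <= 0 for f in flows):
        raise ValueError("invalid design: flows must be > 0")
    design = []
    for c in concentrations:
        for f in flows:
            for rep in range(1, replicates + 1):
                split = "train" if rep == 1 else "test"
                design.append(Condition(float(c), float(f), rep, split))
    return design


# Anchor shape of the relative flow gain: (flow / peak_flow, log relative
# gain).  The gain climbs near-linearly from 0.2x to 1x the peak flow and
# drops again beyond the peak — the characteristic unimodal response of a
# turbulence-driven electrochemical chamber, largest near the peak flow,
# smallest at the lowest flow, and already reduced at 1.2x the peak.
_FLOW_GAIN_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.05, np.log(0.72)),
    (0.2, np.log(0.8487)),
    (0.4, np.log(0.8985)),
    (0.6, np.log(0.9491)),
    (0.8, np.log(0.9759)),
    (1.0, 0.0),
    (1.2, np.log(0.9297)),
    (1.6, np.log(0.84)),
)


def flow_gain(flow, params: SimParams | None = None):
    """Dimensionless sensor gain as a function of pump suction flow.

    A smooth unimodal curve normalized to 1 at ``peak_flow_sccm``: a
    shape-preserving (PCHIP) interpolant through fixed relative-gain
    anchors, evaluated at ``flow / peak_flow_sccm`` and raised to the
    power ``flow_gain_spread`` (so the spread of the curve can be widened
    or narrowed without changing the peak location).  With defaults the
    gain loses ~15% at 0.2x the peak flow and ~7% at 1.2x; the unique
    maximum sits at the peak flow.  Flows beyond the anchor range take
    the boundary values (kept positive).

    Accepts a scalar or array; returns the same shape.
    """
    if params is None:
        params = SimParams()
    f = np.asarray(flow, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("flow must be finite and > 0")
    from scipy.interpolate import PchipInterpolator

    xs = np.array([a for a, _ in _FLOW_GAIN_ANCHORS])
    ys = np.array([b for _, b in _FLOW_GAIN_ANCHORS])
    rel = np.clip(f / params.peak_flow_sccm, xs[0], xs[-1])
    log_g = PchipInterpolator(xs, ys)(rel)
    g = np.exp(params.flow_gain_spread * log_g)
    return float(g) if np.isscalar(flow) else g


def _condition_entropy(condition: Condition) -> int:
    """Stable 32-bit hash of the (concentration, flow, replicate) triple."""
    c, f, rep = condition.key
    text = f"{c:.9g}|{f:.9g}|{rep}"
    return zlib.crc32(text.encode("ascii"))


def simulate_run(
    condition: Condition,
    params: SimParams | None = None,
    sample_rate_hz: float = 10.0,
    duration_s: float = 300.0,
) -> RunSeries:
    """Simulate a single two-channel run under one condition.

    The per-run random stream is derived from ``params.seed`` and a stable
    hash of the condition triple, so a dataset is reproducible run by run
    and independent of simulation order.
    """
    if params is None:
        params = SimParams()
    n = int(round(sample_rate_hz * duration_s))
    if n < 1:
        raise ValueError("sample_rate_hz * duration_s must give at least one sample")
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, _condition_entropy(condition)]))
    t = np.arange(n) / sample_rate_hz
    u = condition.concentration_ppb / params.full_scale_ppb
    a = params.saturation_strength
    saturated = (u - a * u**3) / (1.0 - a)
    amplitude = params.sensitivity * saturated * flow_gain(condition.flow_sccm, params)
    # Run-to-run repeatability: the sensor's effective gain and baseline
    # drift slightly between runs, so run-level summaries do not average
    # down to zero noise the way the per-sample noise does.
    gain_factor = 1.0 + (rng.normal(0.0, params.run_gain_jitter) if params.run_gain_jitter > 0 else 0.0)
    baseline = params.baseline_voltage + (
        rng.normal(0.0, params.run_baseline_jitter_voltage) if params.run_baseline_jitter_voltage > 0 else 0.0
    )
    no_voltage = baseline + gain_factor * amplitude * (1.0 - np.exp(-t / params.rise_time_constant))
    if params.noise_sd_voltage > 0:
        no_voltage = no_voltage + rng.normal(0.0, params.noise_sd_voltage, n)
    flow_reading = np.full(n, condition.flow_sccm, dtype=float)
    if params.flow_noise_sd > 0:
        flow_reading = flow_reading + rng.normal(0.0, params.flow_noise_sd, n)
    return RunSeries(condition, sample_rate_hz, duration_s, no_voltage, flow_reading)


def simulate_dataset(
    design: Iterable[Condition],
    params: SimParams | None = None,
    sample_rate_hz: float = 10.0,
    duration_s: float = 300.0,
) -> list[RunSeries]:
    """Simulate one run per condition of a design.

    Raises ``ValueError`` on duplicate (concentration, flow, replicate)
    triples.  Deterministic given (design, params): same seed, same runs.
    """
    design = list(design)
    keys = [cond.key for cond in design]
    if len(set(keys)) != len(keys):
        raise ValueError("invalid design: duplicate (concentration, flow, replicate) triples")
    return [simulate_run(cond, params, sample_rate_hz, duration_s) for cond in design]
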