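# Methods

## The problem

An active-pumping electronic nose measures trace NO (parts per billion) by
drawing sample gas over an electrochemical sensor.  The sensor's voltage
response depends not only on the gas concentration but also on the pump
suction flow: turbulence over the sensor surface strengthens the reaction,
peaking near 1000 SCCM and falling off toward both 200 and 1200 SCCM.  An
instrument calibrated at one flow therefore misreads at another.  This
package implements a flow-correction pipeline: quantify the flow effect
with a two-factor ANOVA, then calibrate concentration from the joint
(NO-sensor, flow-sensor) reading with two models — a quadratic multiple
regression (MR) and a GA-initialized backpropagation network (GA-BP) —
combined by a response-threshold router into a hybrid calibrator.

## Synthetic bench experiment

Real bench data are not required: `enoseflow.simulate` generates a
factorial campaign that emulates the experiment's structure — six
concentrations {5, 25, 35, 50, 100, 200} ppb crossed with six flows
{200, …, 1200} SCCM, two replicates (replicate 1 trains, replicate 2
tests), each run 5 minutes of two-channel data at 10 Hz.

The noiseless NO channel is

    V(t) = V0 + k · S(c / FS) · g(q) · (1 − exp(−t / τ))

with baseline `V0 = 0.2 V`, full-scale sensitivity `k = 0.8 V`,
`FS = 200 ppb`, and rise time constant `τ = 12 s` (equilibrium well
inside the run; the rise phase leaves the five run summaries ~3% apart).

* **Flow gain `g(q)`** — a shape-preserving (PCHIP) interpolant in
  `q / q_peak` through fixed anchors, normalized to 1 at the peak flow
  (default 1000 SCCM).  It loses ~15% of its peak at 200 SCCM and ~7% at
  1200 SCCM, climbing near-linearly in between: the characteristic
  unimodal response of a turbulence-driven chamber.  The `flow_gain_spread`
  exponent widens or narrows the curve without moving its peak.
* **Saturation `S(u) = (u − a·u³)/(1 − a)`**, `a = 0.12` — the sensor is
  essentially linear over the lower half of its range and loses incremental
  sensitivity toward full scale (per-ppb response at 200 ppb is ~73% of its
  low-range value).  This top-of-range curvature is what gives the
  sigmoid network an advantage over the polynomial at high concentrations,
  and the polynomial an advantage at low ones — the asymmetry the hybrid
  router exploits.
* **Noise** — 10 mV i.i.d. per sample on the NO channel and 5 SCCM on the
  flow channel, plus run-level repeatability jitter (gain ×(1 + N(0, 1.5%)),
  baseline + N(0, 5 mV)).  The jitter is essential: per-sample noise
  averages away over 3000 samples, whereas real runs repeat with a
  coefficient of variation near 1–2%, which the jitter reproduces.

Per-run randomness derives from the master seed plus a stable hash of the
(concentration, flow, replicate) triple, so datasets are bit-reproducible
and independent of simulation order.

What the generator does **not** emulate: temperature/humidity effects,
drift within a run, breath-flow dynamics, cross-sensitivities, and the
non-monotone low-concentration quirks visible in bench tables.  Passing
tests demonstrate the pipeline's statistical machinery and the
qualitative flow-correction story, not instrument-grade accuracy on real
breath data.

## Preprocessing and features

The NO channel is smoothed by a centered moving average (default 51
samples ≈ 5 s; edges use shrunken symmetric windows), the flow channel by
loess — locally weighted linear regression with tricube weights over the
nearest `ceil(span·n)` points (default span 0.3); our implementation
matches statsmodels' LOWESS (`it=0`) to machine precision.  Each smoothed
channel is reduced to five "eigenvalues" — maximum, mean, median, Q1, Q3
(type-7 quartiles) — and the NO/flow eigenvalues are paired by kind,
giving exactly five calibration samples per run (36 training runs → 180
samples).  Flow eigenvalues are divided by 1000 (SCCM → SLPM) so both
model inputs are order 1; concentration stays in ppb.

## ANOVA and LSD

The two-factor decomposition `SST = SSA + SSB + SSAB + SSE` is computed
from cell/marginal means on a balanced r × s × t table (flow × concentration
× repeats; the five eigenvalue kinds times replicates are the repeats,
which is what makes n = 30 observations per flow level).  F statistics
divide each mean square by the error mean square, with p-values from the
F distribution; p below 10⁻³ prints as "<0.001".  Assumption checks are
Brown–Forsythe (median-centered Levene) homogeneity and Shapiro–Wilk
normality.  The LSD comparison sorts level means and reports maximal
contiguous subsets whose extreme means differ by less than
`t₀.₉₇₅,dfE · sqrt(2·MSE/n)`, each annotated with its extreme-pair p-value.
On default synthetic data, 200 SCCM always occupies the lowest subset
alone and 1000 SCCM the highest — the bench ordering.  One caveat: because
the synthetic response is multiplicative in concentration × flow-gain, the
interaction term is significant here, whereas bench data showed it
non-significant; only the two main effects are treated as structural.

## MR calibration

Ordinary least squares (via statsmodels) on either the linear form
(1, x1, x2) or the quadratic form (1, x1, x2, x1·x2, x2²).  The quadratic
term set deliberately omits x1² to match the form used for flow
correction in this instrument class; a `full_quadratic` flag adds it.
Model selection prefers candidates whose coefficient t-tests and overall
F-test are all significant at α = 0.05, then lowest AIC
(`n·ln(SSE/n) + 2(k+1)`, Gaussian profile form), then lowest RMSE.
Because the quadratic has no x1² term, OLS redistributes any
concentration curvature into a characteristic low/high-end residual tilt
— the structural weakness the hybrid compensates.

## GA-BP calibration

A 2–2–1 network: logistic-sigmoid hidden units
(`h_j = σ(Σ_i ω_ij x_i − θ_j)`), identity output
(`ŷ = Σ_j w_j h_j − θ_o`); identity output suits regression onto an
unbounded scaled concentration.  Training minimizes
`E = (1/m) Σ_k ½(ŷ_k − y_k)²` by full-batch gradient descent.  Inputs and
output are min–max scaled to [0, 1] using the fit split's ranges (stored
in the model and inverted on prediction).  The 180 training samples are
randomly halved (seeded) into 90 fit + 90 validation samples.

Initial weights/thresholds come from a genetic algorithm over the
9-gene chromosome (weights then thresholds): population 5, 50
generations, tournament selection (size 2), per-gene blend crossover
(p = 0.8), Gaussian mutation (p = 0.1, scale 0.1), elitism 1, genes
initialized uniform in [−1, 1].  Fitness is the validation error after a
300-epoch inner backprop refinement — "optimal initial weights" are ones
that train well; raw-initial fitness is nearly flat and is available via
`fitness="initial"`.  Fitness values are cached per chromosome, so the
elitist best-fitness trajectory is provably non-increasing.

Numerical settings: learning rate 0.5, up to 20 000 epochs, stopping when
the per-epoch decrease of E falls below 10⁻¹².  These were set by
measuring convergence on [0, 1]-scaled data: smaller rates (e.g. 0.05)
leave E well above the basin optimum even after tens of thousands of
epochs.  Gradients are verified against central finite differences in the
test suite.

## Hybrid routing and metrics

The router threshold τ is the mean moving-average-smoothed NO response of
the training run(s) at 50 ppb and 1000 SCCM.  A sample with x1 < τ is
predicted by MR, with x1 ≥ τ by GA-BP (the tie is measure-zero; it goes
to GA-BP).  Every hybrid prediction is bit-identical to the routed
sub-model's output.

Metrics: R², MSE, RMSE in ppb, and precision as ±%FS = max |error| / FS
× 100 with FS = 200 ppb (largest design concentration); a mean-absolute
variant is available via `error_stat="mean"`.  The uncorrected reference
("flow-blind baseline") fits a single line y ~ x1 on the training samples
at the peak-gain flow and applies it at every flow; on default synthetic
data it sits near 20 %FS, while the hybrid typically reaches 9–12 %FS and
roughly half the baseline's RMSE.

## Design choices and limitations

* The generator's flow-gain anchors and saturation strength are fixed
  structural defaults of the synthetic study, chosen so the simulated
  campaign reproduces the qualitative bench structure (flow ordering,
  flow-blind error ≳ 15 %FS, run repeatability 1–2% CV, complementary
  MR/GA-BP skill); they are not fitted to any dataset at run time.
* With only 9 parameters, the 2–2–1 network cannot jointly represent
  saturation in x1 and unimodal modulation in x2; its residual floor at
  the (200 ppb, 200 SCCM) corner is several ppb no matter how it is
  trained.  Conversely the quadratic-without-x1² spreads top-range
  curvature into a low-end tilt.  The hybrid mitigates but does not
  eliminate either defect: expect it to track the better single model to
  within ~5–15% RMSE rather than strictly dominate it on every draw of
  the synthetic experiment.
* The ANOVA machinery is balanced-design only (no Type II/III sums of
  squares); LSD is the only post-hoc comparison; no regularized or robust
  regression variants.
* An import adapter for external bench recordings is limited to the
  documented per-run CSV layout (`runio`); other layouts must be
  converted first.
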