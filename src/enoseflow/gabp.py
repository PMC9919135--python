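"""Backpropagation network with genetic-algorithm-chosen initial parameters.

The calibrator is a small feedforward network — two inputs (NO-sensor
eigenvalue, scaled flow eigenvalue), one hidden layer of two logistic
neurons, one linear output — trained by full-batch gradient descent on

    E = (1/m) * sum_k E_k,     E_k = 1/2 * (yhat_k - y_k)^2.

Gradient descent from random parameters can stall in poor local minima,
so the initial weights and thresholds are picked by a small genetic
algorithm: chromosomes are the flattened parameter vector, fitness is the
validation-set error (by default measured after a short inner
backpropagation refinement, so "good initial weights" means weights that
train well), and the usual selection / crossover / mutation operators with
elitism evolve the population.

Neuron convention: hidden_j = sigmoid(sum_i w_in[i, j] * x_i - theta_h[j]);
output = sum_j w_out[j] * hidden_j - theta_o (thresholds are subtracted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocess import CalibrationSample

__all__ = [
    "Architecture",
    "BPNetwork",
    "GAConfig",
    "GABPModel",
    "forward",
    "sample_error",
    "mean_error",
    "gradients",
    "backprop_train",
    "encode",
    "decode",
    "chromosome_length",
    "ga_optimize",
    "train_gabp",
    "predict_gabp",
]


@dataclass(frozen=True)
class Architecture:
    n_inputs: int = 2
    n_hidden: int = 2
    n_outputs: int = 1  # single linear output

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1 or self.n_outputs != 1:
            raise ValueError("architecture must have >=1 input, >=1 hidden neuron, and exactly 1 output")


@dataclass
class BPNetwork:
    """Network parameters: input->hidden weights, hidden thresholds,
    hidden->output weights, output threshold."""

    w_in: np.ndarray       # (n_inputs, n_hidden)
    theta_h: np.ndarray    # (n_hidden,)
    w_out: np.ndarray      # (n_hidden,)
    theta_o: float

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.theta_h = np.asarray(self.theta_h, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.theta_o = float(self.theta_o)
        if self.w_in.ndim != 2:
            raise ValueError("w_in must be 2-D (n_inputs, n_hidden)")
        nh = self.w_in.shape[1]
        if self.theta_h.shape != (nh,) or self.w_out.shape != (nh,):
            raise ValueError("theta_h and w_out must match the hidden width")
        if not all(np.all(np.isfinite(a)) for a in (self.w_in, self.theta_h, self.w_out, [self.theta_o])):
            raise ValueError("network parameters must be finite")

    @property
    def architecture(self) -> Architecture:
        return Architecture(self.w_in.shape[0], self.w_in.shape[1], 1)

    def copy(self) -> "BPNetwork":
        return BPNetwork(self.w_in.copy(), self.theta_h.copy(), self.w_out.copy(), self.theta_o)

    @classmethod
    def zeros(cls, arch: Architecture = Architecture()) -> "BPNetwork":
        return cls(np.zeros((arch.n_inputs, arch.n_hidden)), np.zeros(arch.n_hidden), np.zeros(arch.n_hidden), 0.0)

    @classmethod
    def random(cls, arch: Architecture, rng: np.random.Generator, scale: float = 1.0) -> "BPNetwork":
        return decode(rng.uniform(-scale, scale, chromosome_length(arch)), arch)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _hidden(net: BPNetwork, X: np.ndarray) -> np.ndarray:
    return _sigmoid(X @ net.w_in - net.theta_h)


def forward(net: BPNetwork, x):
    """Network output for a single input pair or a batch of rows."""
    X = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("inputs must be finite")
    single = X.ndim == 1
    Xb = X[None, :] if single else X
    out = _hidden(net, Xb) @ net.w_out - net.theta_o
    return float(out[0]) if single else out


def sample_error(net: BPNetwork, x, y) -> float:
    """Per-sample squared error E_k = 1/2 (yhat - y)^2."""
    return 0.5 * (forward(net, np.asarray(x, dtype=float)) - float(y)) ** 2


def mean_error(net: BPNetwork, X, y) -> float:
    """Mean accumulated error E over a sample set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("sample set must be non-empty")
    resid = forward(net, X) - y
    return float(0.5 * np.mean(resid**2))


def gradients(net: BPNetwork, X, y) -> BPNetwork:
    """Analytic gradient of E with respect to every parameter, packaged in
    a network-shaped container."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = y.size
    H = _hidden(net, X)                       # (m, nh)
    resid = (H @ net.w_out - net.theta_o) - y  # (m,)
    dy = resid / m
    g_wout = H.T @ dy
    g_thetao = -float(dy.sum())
    delta = dy[:, None] * net.w_out[None, :] * H * (1.0 - H)  # (m, nh)
    g_win = X.T @ delta
    g_thetah = -delta.sum(axis=0)
    return BPNetwork(g_win, g_thetah, g_wout, g_thetao)


def backprop_train(
    net: BPNetwork,
    X,
    y,
    learning_rate: float = 0.5,
    max_epochs: int = 20000,
    tolerance: float = 1e-9,
) -> tuple[BPNetwork, np.ndarray]:
    """Full-batch gradient descent on E.

    Stops after ``max_epochs`` or when the epoch-to-epoch decrease of E
    falls below ``tolerance``.  Returns the trained network and the E
    trajectory (one entry per evaluated epoch, including the final state).
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    net = net.copy()
    trajectory = [mean_error(net, X, y)]
    for _ in range(max_epochs):
        g = gradients(net, X, y)
        net.w_in -= learning_rate * g.w_in
        net.theta_h -= learning_rate * g.theta_h
        net.w_out -= learning_rate * g.w_out
        net.theta_o -= learning_rate * g.theta_o
        e = mean_error(net, X, y)
        trajectory.append(e)
        if abs(trajectory[-2] - e) < tolerance:
            break
    return net, np.asarray(trajectory)


def chromosome_length(arch: Architecture = Architecture()) -> int:
    """Genes: all weights then all thresholds (9 for the default 2-2-1 net)."""
    return arch.n_inputs * arch.n_hidden + arch.n_hidden + arch.n_hidden + 1


def encode(net: BPNetwork) -> np.ndarray:
    """Flatten a network into a gene vector: w_in (row-major), w_out,
    theta_h, theta_o."""
    return np.concatenate([net.w_in.ravel(), net.w_out, net.theta_h, [net.theta_o]])


def decode(genes, arch: Architecture = Architecture()) -> BPNetwork:
    """Inverse of :func:`encode`."""
    genes = np.asarray(genes, dtype=float)
    if genes.shape != (chromosome_length(arch),):
        raise ValueError(f"encoding error: expected {chromosome_length(arch)} genes, got {genes.shape}")
    ni, nh = arch.n_inputs, arch.n_hidden
    pos = ni * nh
    w_in = genes[:pos].reshape(ni, nh)
    w_out = genes[pos : pos + nh]
    theta_h = genes[pos + nh : pos + 2 * nh]
    theta_o = genes[-1]
    return BPNetwork(w_in.copy(), theta_h.copy(), w_out.copy(), float(theta_o))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults: population 5, 50 generations).

    ``fitness`` selects how a chromosome is scored: ``"refined"`` runs
    ``inner_epochs`` of backpropagation on the fit split before measuring
    the validation error (initial weights that train well win); ``"initial"``
    scores the raw decoded network.
    """

    population_size: int = 5
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1
    tournament_size: int = 2
    elitism: int = 1
    init_range: float = 1.0
    fitness: str = "refined"
    inner_epochs: int = 300
    inner_learning_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")
        if self.fitness not in ("refined", "initial"):
            raise ValueError("fitness must be 'refined' or 'initial'")


def ga_optimize(
    X_fit,
    y_fit,
    X_val,
    y_val,
    config: GAConfig = GAConfig(),
    arch: Architecture = Architecture(),
    rng: np.random.Generator | None = None,
) -> tuple[BPNetwork, np.ndarray]:
    """Evolve initial network parameters; returns (best network decoded
    from its chromosome, best-fitness-per-generation history).

    Tournament selection, arithmetic (per-gene blend) crossover, Gaussian
    mutation, elitism.  Fitness values are cached per chromosome, so with
    ``elitism >= 1`` the best fitness is non-increasing across generations.
    """
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size == 0:
        raise ValueError("validation split must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    length = chromosome_length(arch)

    def fitness(genes: np.ndarray) -> float:
        net = decode(genes, arch)
        if config.fitness == "refined":
            net, _ = backprop_train(
                net, X_fit, y_fit,
                learning_rate=config.inner_learning_rate,
                max_epochs=config.inner_epochs,
                tolerance=0.0,
            )
        return mean_error(net, X_val, y_val)

    pop = [rng.uniform(-config.init_range, config.init_range, length) for _ in range(config.population_size)]
    fits = np.array([fitness(g) for g in pop])
    history = []

    def tournament() -> np.ndarray:
        idx = rng.integers(0, config.population_size, config.tournament_size)
        return pop[idx[np.argmin(fits[idx])]]

    for _ in range(config.generations):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        new_fits = [fits[i] for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_prob:
                u = rng.random(length)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mask = rng.random(length) < config.mutation_prob
            if mask.any():
                child[mask] += rng.normal(0.0, config.mutation_scale, int(mask.sum()))
            new_pop.append(child)
            new_fits.append(fitness(child))
        pop, fits = new_pop, np.asarray(new_fits)
        history.append(float(fits.min()))

    best = int(np.argmin(fits))
    return decode(pop[best], arch), np.asarray(history)


@dataclass
class GABPModel:
    """Trained GA-BP calibrator with its min-max scaling metadata.

    Inputs and the output are min-max scaled to [0, 1] using the fit
    split's ranges before the network sees them; predictions invert the
    output scaling back to ppb.
    """

    net: BPNetwork
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    ga_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    bp_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    validation_error: float = np.nan
    n_fit: int = 0
    n_val: int = 0

    def predict(self, x1, x2):
        return predict_gabp(self, x1, x2)

    def to_dict(self) -> dict:
        return {
            "kind": "gabp",
            "architecture": [self.net.w_in.shape[0], self.net.w_in.shape[1], 1],
            "w_in": self.net.w_in.tolist(),
            "theta_h": self.net.theta_h.tolist(),
            "w_out": self.net.w_out.tolist(),
            "theta_o": self.net.theta_o,
            "x_min": np.asarray(self.x_min).tolist(),
            "x_range": np.asarray(self.x_range).tolist(),
            "y_min": self.y_min,
            "y_range": self.y_range,
            "ga_history": np.asarray(self.ga_history).tolist(),
            "bp_final_error": float(self.bp_trajectory[-1]) if len(self.bp_trajectory) else None,
            "validation_error": None if np.isnan(self.validation_error) else self.validation_error,
            "n_fit": self.n_fit,
            "n_val": self.n_val,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GABPModel":
        net = BPNetwork(
            np.asarray(data["w_in"], dtype=float),
            np.asarray(data["theta_h"], dtype=float),
            np.asarray(data["w_out"], dtype=float),
            float(data["theta_o"]),
        )
        return cls(
            net=net,
            x_min=np.asarray(data["x_min"], dtype=float),
            x_range=np.asarray(data["x_range"], dtype=float),
            y_min=float(data["y_min"]),
            y_range=float(data["y_range"]),
            ga_history=np.asarray(data.get("ga_history", []), dtype=float),
            validation_error=float(data["validation_error"]) if data.get("validation_error") is not None else np.nan,
            n_fit=int(data.get("n_fit", 0)),
            n_val=int(data.get("n_val", 0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GABPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_gabp(
    samples: Sequence[CalibrationSample],
    ga: GAConfig = GAConfig(),
    arch: Architecture = Architecture(),
    learning_rate: float = 0.5,
    max_epochs: int = 20000,
    tolerance: float = 1e-12,
    seed: int = 0,
) -> GABPModel:
    """Full GA-BP training from calibration samples.

    The samples are randomly halved (seeded) into a fit split and a
    validation split (180 samples -> two groups of 90); inputs and output
    are min-max scaled to [0, 1] using the fit split's ranges; the GA
    chooses initial parameters; backpropagation trains to convergence on
    the fit split.
    """
    samples = list(samples)
    m = len(samples)
    if m < 4:
        raise ValueError(f"too few samples: need at least 4, got {m}")
    X = np.array([[s.x1, s.x2] for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=float)

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    perm = rng.permutation(m)
    n_fit = m // 2
    fit_idx, val_idx = perm[:n_fit], perm[n_fit:]

    x_min = X[fit_idx].min(axis=0)
    x_range = X[fit_idx].max(axis=0) - x_min
    x_range = np.where(x_range == 0, 1.0, x_range)
    y_min = float(y[fit_idx].min())
    y_range = float(y[fit_idx].max() - y_min) or 1.0

    Xs = (X - x_min) / x_range
    ys = (y - y_min) / y_range

    net0, history = ga_optimize(Xs[fit_idx], ys[fit_idx], Xs[val_idx], ys[val_idx], ga, arch, rng)
    net, trajectory = backprop_train(net0, Xs[fit_idx], ys[fit_idx], learning_rate, max_epochs, tolerance)
    return GABPModel(
        net=net,
        x_min=x_min,
        x_range=x_range,
        y_min=y_min,
        y_range=y_range,
        ga_history=history,
        bp_trajectory=trajectory,
        validation_error=mean_error(net, Xs[val_idx], ys[val_idx]),
        n_fit=len(fit_idx),
        n_val=len(val_idx),
    )


def predict_gabp(model: GABPModel, x1, x2):
    """Predict concentration (ppb): scale inputs, run the network, invert
    the output scaling."""
    x1a = np.atleast_1d(np.asarray(x1, dtype=float))
    x2a = np.atleast_1d(np.asarray(x2, dtype=float))
    X = np.column_stack([x1a, x2a])
    Xs = (X - model.x_min) / model.x_range
    out = forward(model.net, Xs) * model.y_range + model.y_min
    return float(out[0]) if np.isscalar(x1) or np.asarray(x1).ndim == 0 else out
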