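"""Weight optimisation: generational GA (neuroevolution) and full-batch BPTT.

The genetic algorithm keeps a population of complete genomes (all weights
and biases), scores each with the exponential fitness W = 1.5^(w a), and
forms the next generation by fitness-proportional (roulette-wheel)
sampling with replacement followed by per-weight Gaussian mutation of
every offspring — no elitism, no recombination.  Defaults: population 100,
per-weight mutation probability 0.01, mutation variance 0.1.

Backpropagation trains a single network by plain full-batch gradient
descent on the mean squared error between final-timestep outputs and the
+/-1 target matrix, with exact gradients backpropagated through all four
timesteps (an "epoch" is one full-batch update over all 24 episodes).
Adam is available as an alternative optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acp_task import EpisodeSet
from .elman_rnn import (
    GENOME_SIZE,
    N_HIDDEN,
    N_IN,
    N_OUT,
    RNNParams,
    _init_from_rng,
    target_matrix,
)


@dataclass
class GAConfig:
    population_size: int = 100
    mutation_rate: float = 0.01
    mutation_variance: float = 0.1
    max_generations: int = 2000
    seed: int = 0
    stop_at_perfect: bool = True
    init_scheme: str = "kaiming"
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.mutation_variance < 0:
            raise ValueError("mutation_variance must be nonnegative")


@dataclass
class BPConfig:
    learning_rate: float = 0.1
    max_epochs: int = 5000
    seed: int = 0
    stop_at_perfect: bool = True
    optimizer: str = "gd"
    init_scheme: str = "kaiming"
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    """Per-iteration progress of one training run.

    ``first_perfect`` is the 0-based generation/epoch index at which a
    network first classified all episodes correctly, or None.  Snapshots
    hold copies of the recurrent matrix M at fixed intervals (for
    weight-trajectory plots).
    """

    method: str
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_accuracy: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    first_perfect: int | None = None
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.best_accuracy)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "best_accuracy": self.best_accuracy,
            }
        )
        if self.loss:
            df["loss"] = self.loss
        return df


# ---------------------------------------------------------------------------
# genetic algorithm


def mutate(genome: RNNParams, cfg: GAConfig, rng: np.random.Generator) -> RNNParams:
    """Per-weight point mutation: with probability ``mutation_rate`` each
    scalar parameter receives an additive N(0, mutation_variance) offset.
    The input genome is left untouched."""
    vec = genome.to_vector()
    mask = rng.random(vec.shape) < cfg.mutation_rate
    offsets = rng.normal(0.0, np.sqrt(cfg.mutation_variance), vec.shape)
    return RNNParams.from_vector(vec + mask * offsets)


def select_parents(
    fitnesses: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Roulette-wheel selection: i.i.d. draws with replacement, probability
    proportional to fitness."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(fitnesses)) or np.any(fitnesses <= 0):
        raise ValueError("fitnesses must be finite and strictly positive")
    p = fitnesses / fitnesses.sum()
    return rng.choice(len(fitnesses), size=count, p=p)


def _unpack_population(pop: np.ndarray):
    """Views of a [P, GENOME_SIZE] population as batched weight arrays."""
    p = pop.shape[0]
    o = 0
    w_in = pop[:, o : o + N_HIDDEN * N_IN].reshape(p, N_HIDDEN, N_IN)
    o += N_HIDDEN * N_IN
    m = pop[:, o : o + N_HIDDEN * N_HIDDEN].reshape(p, N_HIDDEN, N_HIDDEN)
    o += N_HIDDEN * N_HIDDEN
    w_out = pop[:, o : o + N_OUT * N_HIDDEN].reshape(p, N_OUT, N_HIDDEN)
    o += N_OUT * N_HIDDEN
    b_h = pop[:, o : o + N_HIDDEN]
    o += N_HIDDEN
    b_o = pop[:, o : o + N_OUT]
    return w_in, m, w_out, b_h, b_o


def evaluate_population(
    pop: np.ndarray, frames: np.ndarray, targets: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised scoring of a whole population on the whole episode set.

    pop: [P, GENOME_SIZE]; frames: [n, T, 4]; targets: [n, 8]; labels: [n].
    Returns (W [P], w [P], a [P]).
    """
    w_in, m, w_out, b_h, b_o = _unpack_population(pop)
    n = frames.shape[0]
    p = pop.shape[0]
    h = np.zeros((p, n, N_HIDDEN))
    for t in range(frames.shape[1]):
        inp = np.einsum("phi,ni->pnh", w_in, frames[:, t, :])
        rec = np.einsum("phk,pnk->pnh", m, h)
        h = np.tanh(inp + rec + b_h[:, None, :])
    y = np.tanh(np.einsum("poh,pnh->pno", w_out, h) + b_o[:, None, :])
    d = y - targets[None, :, :]
    e = np.sum(d * d, axis=(1, 2))
    w = 1.0 - e / (targets.shape[0] * targets.shape[1])
    a = np.sum(np.argmax(y, axis=2) == labels[None, :], axis=1)
    fitness = 1.5 ** (w * a)
    return fitness, w, a.astype(int)


def evolve(cfg: GAConfig, data: EpisodeSet) -> tuple[RNNParams, TrainingHistory]:
    """Run the generational GA; returns the best genome seen and the history.

    The loop evaluates all P genomes, logs best/mean fitness and best
    accuracy, then replaces the population with P roulette-wheel parent
    draws each passed through mutation.  With ``stop_at_perfect`` the loop
    ends at the first generation containing a 24/24 classifier.
    """
    rng = np.random.default_rng(cfg.seed)
    frames, labels = data.frames, data.labels
    targets = target_matrix(data)
    pop = np.stack(
        [_init_from_rng(rng, cfg.init_scheme).to_vector() for _ in range(cfg.population_size)]
    )
    history = TrainingHistory(method="GA")
    # best genome seen, ranked by (accuracy, fitness); with continued
    # evolution past the first perfect classifier this tracks the most
    # refined perfect genome rather than an early one
    best_vec, best_key = pop[0].copy(), (-1, -np.inf)
    sqrt_var = np.sqrt(cfg.mutation_variance)

    for gen in range(cfg.max_generations):
        fitness, w, a = evaluate_population(pop, frames, targets, labels)
        gen_best = int(np.lexsort((fitness, a))[-1])
        history.best_fitness.append(float(fitness[gen_best]))
        history.mean_fitness.append(float(fitness.mean()))
        history.best_accuracy.append(int(a.max()))
        key = (int(a[gen_best]), float(fitness[gen_best]))
        if key >= best_key:
            best_key = key
            best_vec = pop[gen_best].copy()
        if cfg.snapshot_every and gen % cfg.snapshot_every == 0:
            history.snapshots.append(
                (gen, RNNParams.from_vector(pop[gen_best]).m.copy())
            )
        if a.max() == data.n:
            if history.first_perfect is None:
                history.first_perfect = gen
            if cfg.stop_at_perfect:
                break
        # next generation: roulette-wheel parents, every offspring mutated
        parents = select_parents(fitness, cfg.population_size, rng)
        pop = pop[parents]
        mask = rng.random(pop.shape) < cfg.mutation_rate
        offsets = rng.normal(0.0, sqrt_var, pop.shape)
        pop = pop + mask * offsets

    return RNNParams.from_vector(best_vec), history


# ---------------------------------------------------------------------------
# backpropagation through time


def bptt_gradients(params: RNNParams, data: EpisodeSet) -> RNNParams:
    """Exact full-batch gradients of the MSE loss, shaped like the parameters.

    Loss = mean over all n*m output entries of (O - A)^2, with O the
    final-timestep outputs; gradients are backpropagated through all four
    recurrent updates and accumulated over all episodes.
    """
    frames, targets = data.frames, target_matrix(data)
    n, n_t, _ = frames.shape

    h = np.zeros((n, N_HIDDEN))
    hs = [h]
    for t in range(n_t):
        h = np.tanh(frames[:, t, :] @ params.w_in.T + hs[-1] @ params.m.T + params.b_h)
        hs.append(h)
    y = np.tanh(hs[-1] @ params.w_out.T + params.b_o)

    g_w_in = np.zeros_like(params.w_in)
    g_m = np.zeros_like(params.m)
    g_w_out = np.zeros_like(params.w_out)
    g_b_h = np.zeros_like(params.b_h)
    g_b_o = np.zeros_like(params.b_o)

    dz_o = 2.0 * (y - targets) / targets.size * (1.0 - y * y)
    g_w_out += dz_o.T @ hs[-1]
    g_b_o += dz_o.sum(axis=0)
    dh = dz_o @ params.w_out

    for t in range(n_t - 1, -1, -1):
        dz = dh * (1.0 - hs[t + 1] * hs[t + 1])
        g_w_in += dz.T @ frames[:, t, :]
        g_m += dz.T @ hs[t]
        g_b_h += dz.sum(axis=0)
        dh = dz @ params.m

    if not all(
        np.all(np.isfinite(g)) for g in (g_w_in, g_m, g_w_out, g_b_h, g_b_o)
    ):
        raise FloatingPointError("non-finite gradients")
    return RNNParams(w_in=g_w_in, m=g_m, w_out=g_w_out, b_h=g_b_h, b_o=g_b_o)


def mse_loss(params: RNNParams, data: EpisodeSet) -> float:
    """Mean squared error of final-timestep outputs against the target matrix."""
    from .elman_rnn import run_batch

    _, y = run_batch(params, data.frames)
    targets = target_matrix(data)
    return float(np.mean((y - targets) ** 2))


def train_bp(
    cfg: BPConfig, data: EpisodeSet, init: RNNParams | None = None
) -> tuple[RNNParams, TrainingHistory]:
    """Full-batch gradient-descent training (optionally Adam).

    One epoch = one gradient step on the whole 24-episode batch.  Raises
    ``FloatingPointError`` on divergence (non-finite loss or gradients).
    """
    from .elman_rnn import run_batch

    params = (init.copy() if init is not None
              else _init_from_rng(np.random.default_rng(cfg.seed), cfg.init_scheme))
    targets = target_matrix(data)
    history = TrainingHistory(method="BP")

    if cfg.optimizer == "adam":
        m1 = np.zeros(GENOME_SIZE)
        m2 = np.zeros(GENOME_SIZE)
        beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(cfg.max_epochs):
        _, y = run_batch(params, data.frames)
        loss = float(np.mean((y - targets) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        a = int(np.sum(np.argmax(y, axis=1) == data.labels))
        w = 1.0 - loss  # E/(n m) equals the MSE over n x m entries
        fitness = float(1.5 ** (w * a))
        history.best_fitness.append(fitness)
        history.mean_fitness.append(fitness)
        history.best_accuracy.append(a)
        history.loss.append(loss)
        if cfg.snapshot_every and epoch % cfg.snapshot_every == 0:
            history.snapshots.append((epoch, params.m.copy()))
        if a == data.n:
            if history.first_perfect is None:
                history.first_perfect = epoch
            if cfg.stop_at_perfect:
                break

        grads = bptt_gradients(params, data)
        if cfg.optimizer == "gd":
            new_vec = params.to_vector() - cfg.learning_rate * grads.to_vector()
        else:
            g = grads.to_vector()
            m1 = beta1 * m1 + (1 - beta1) * g
            m2 = beta2 * m2 + (1 - beta2) * g * g
            m1_hat = m1 / (1 - beta1 ** (epoch + 1))
            m2_hat = m2 / (1 - beta2 ** (epoch + 1))
            new_vec = params.to_vector() - cfg.learning_rate * m1_hat / (np.sqrt(m2_hat) + eps)
        params = RNNParams.from_vector(new_vec)

    return params, history
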