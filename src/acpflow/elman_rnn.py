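"""The 4-16-8 Elman recurrent network and its performance score.

Architecture: 4 sensors feed a 16-node recurrent (hidden) layer through
``W_in``; the hidden layer feeds back on itself through the recurrent
matrix ``M`` and forward into 8 output nodes through ``W_out``.  Every
hidden and output node sums its inputs, adds a bias, and applies tanh.
The hidden state starts at zero before each episode.

Performance on the 24-episode task is scored from the final-timestep
outputs O against one-hot targets A (+1 at the true class, 0 elsewhere):

    E = sum_ij (O - A)_ij^2           squared error
    w = 1 - E / (n m)                 normalised fitness (n=24, m=8)
    a = number of correctly classified episodes (argmax readout)
    W = 1.5^(w a)                     selection fitness (always positive)

``NoiseSpec`` supports the weight-perturbation protocol: targeted entries
of M are shifted by a fresh one-sided uniform draw from U[0, r] at every
computational update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np

from .acp_task import EpisodeSet, Episode, N_CLASSES

N_IN = 4
N_HIDDEN = 16
N_OUT = 8

#: flat genome layout: W_in, M, W_out, b_h, b_o, each row-major
GENOME_SIZE = N_HIDDEN * N_IN + N_HIDDEN * N_HIDDEN + N_OUT * N_HIDDEN + N_HIDDEN + N_OUT

_SLICES = {}
_off = 0
for _name, _shape in [
    ("w_in", (N_HIDDEN, N_IN)),
    ("m", (N_HIDDEN, N_HIDDEN)),
    ("w_out", (N_OUT, N_HIDDEN)),
    ("b_h", (N_HIDDEN,)),
    ("b_o", (N_OUT,)),
]:
    _size = int(np.prod(_shape))
    _SLICES[_name] = (slice(_off, _off + _size), _shape)
    _off += _size
assert _off == GENOME_SIZE


@dataclass
class RNNParams:
    """All weights and biases of the 4-16-8 Elman network (the GA genome).

    ``m`` is oriented (row = target node, column = source node): entry
    ``m[j, i]`` is the weight of the edge i -> j within the recurrent layer.
    """

    w_in: np.ndarray   # [16, 4]
    m: np.ndarray      # [16, 16]
    w_out: np.ndarray  # [8, 16]
    b_h: np.ndarray    # [16]
    b_o: np.ndarray    # [8]

    def __post_init__(self) -> None:
        expected = {
            "w_in": (N_HIDDEN, N_IN),
            "m": (N_HIDDEN, N_HIDDEN),
            "w_out": (N_OUT, N_HIDDEN),
            "b_h": (N_HIDDEN,),
            "b_o": (N_OUT,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical genome layout."""
        return np.concatenate(
            [self.w_in.ravel(), self.m.ravel(), self.w_out.ravel(), self.b_h, self.b_o]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "RNNParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (GENOME_SIZE,):
            raise ValueError(f"genome must have length {GENOME_SIZE}, got {vec.shape}")
        kwargs = {
            name: vec[sl].reshape(shape) for name, (sl, shape) in _SLICES.items()
        }
        return cls(**kwargs)

    def copy(self) -> "RNNParams":
        return replace(
            self,
            w_in=self.w_in.copy(),
            m=self.m.copy(),
            w_out=self.w_out.copy(),
            b_h=self.b_h.copy(),
            b_o=self.b_o.copy(),
        )

    def save_text(self, path: str | Path) -> None:
        np.savetxt(path, self.to_vector())

    @classmethod
    def load_text(cls, path: str | Path) -> "RNNParams":
        return cls.from_vector(np.loadtxt(path))


@dataclass(frozen=True)
class NoiseSpec:
    """One-sided uniform weight perturbation applied to entries of M.

    Each targeted weight is shifted by a draw from U[0, r], redrawn at
    every step() update.  ``sharing='shared'`` draws one common offset per
    update for all targets; the default draws independently per target.
    """

    targets: tuple[tuple[int, int], ...]
    r: float
    sharing: str = "independent"

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("noise bound r must be nonnegative")
        if self.sharing not in ("independent", "shared"):
            raise ValueError(f"unknown sharing mode {self.sharing!r}")
        for (i, j) in self.targets:
            if not (0 <= i < N_HIDDEN and 0 <= j < N_HIDDEN):
                raise ValueError(f"target ({i}, {j}) outside the {N_HIDDEN}x{N_HIDDEN} matrix")
        object.__setattr__(self, "targets", tuple(sorted(set(map(tuple, self.targets)))))


@dataclass(frozen=True)
class PerformanceRecord:
    """Squared error E, normalised fitness w, accuracy count a, fitness W."""

    e: float
    w: float
    a: int
    fitness: float


@dataclass
class StateTrace:
    """Recorded hidden states and within-episode state transitions.

    ``states`` is [n_episodes x 4 timesteps x 16 nodes] (post-tanh values).
    Transitions pair h_t with h_{t+1} for t = 0, 1, 2 within each episode
    only — the pre-episode zero state is not a sample — giving 24 x 3 = 72
    pairs for the full task.
    """

    states: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.states.shape[0] * self.states.shape[1]

    @property
    def transitions(self) -> tuple[np.ndarray, np.ndarray]:
        """(from, to) arrays, each [n_episodes*3 x 16]."""
        frm = self.states[:, :-1, :].reshape(-1, N_HIDDEN)
        to = self.states[:, 1:, :].reshape(-1, N_HIDDEN)
        return frm, to


def target_matrix(data: EpisodeSet) -> np.ndarray:
    """Expected-answer matrix A: one-hot, +1 at the true class, 0 elsewhere.

    With 0 off-target values, a randomly initialised network (outputs near
    zero) scores w ~ 1 - 1/m > 0, so the exponential fitness W = 1.5^(w a)
    rewards accuracy from the first generation.  A -1 off-target coding
    instead makes w negative at initialisation, which actively punishes
    accurate classifiers and stalls roulette-wheel selection.
    """
    a = np.zeros((data.n, N_CLASSES))
    a[np.arange(data.n), data.labels] = 1.0
    return a


def init_network(seed: int, scheme: str = "kaiming") -> RNNParams:
    """Random fan-in-scaled weight initialisation; biases start at zero.

    ``kaiming``: N(0, 2/fan_in) per weight matrix (He et al. style);
    ``xavier``: N(0, 2/(fan_in + fan_out)) (Glorot style).
    """
    rng = np.random.default_rng(seed)
    return _init_from_rng(rng, scheme)


def _init_from_rng(rng: np.random.Generator, scheme: str = "kaiming") -> RNNParams:
    def std(fan_in: int, fan_out: int) -> float:
        if scheme == "kaiming":
            return np.sqrt(2.0 / fan_in)
        if scheme == "xavier":
            return np.sqrt(2.0 / (fan_in + fan_out))
        raise ValueError(f"unknown initialisation scheme {scheme!r}")

    return RNNParams(
        w_in=rng.normal(0.0, std(N_IN, N_HIDDEN), (N_HIDDEN, N_IN)),
        m=rng.normal(0.0, std(N_HIDDEN, N_HIDDEN), (N_HIDDEN, N_HIDDEN)),
        w_out=rng.normal(0.0, std(N_HIDDEN, N_OUT), (N_OUT, N_HIDDEN)),
        b_h=np.zeros(N_HIDDEN),
        b_o=np.zeros(N_OUT),
    )


def _noisy_m_batch(
    m: np.ndarray, noise: NoiseSpec, n_batch: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-episode perturbed copies of M for one update, shape [n_batch, 16, 16]."""
    mt = np.broadcast_to(m, (n_batch, N_HIDDEN, N_HIDDEN)).copy()
    k = len(noise.targets)
    if k == 0 or noise.r == 0:
        return mt
    if noise.sharing == "shared":
        offsets = np.repeat(rng.uniform(0.0, noise.r, (n_batch, 1)), k, axis=1)
    else:
        offsets = rng.uniform(0.0, noise.r, (n_batch, k))
    rows = np.array([t[0] for t in noise.targets])
    cols = np.array([t[1] for t in noise.targets])
    mt[:, rows, cols] += offsets
    return mt


def step(
    params: RNNParams,
    h_prev: np.ndarray,
    x: np.ndarray,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrent update: h = tanh(W_in x + M h_prev + b_h), y = tanh(W_out h + b_o).

    With a ``NoiseSpec``, the targeted entries of M receive fresh U[0, r]
    offsets for this update; ``params`` is never modified in place.
    """
    h_prev = np.asarray(h_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(h_prev)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite inputs to step()")
    if noise is not None and noise.r > 0 and noise.targets:
        if rng is None:
            raise ValueError("a NoiseSpec with r > 0 requires an rng")
        m = _noisy_m_batch(params.m, noise, 1, rng)[0]
    else:
        m = params.m
    h = np.tanh(params.w_in @ x + m @ h_prev + params.b_h)
    y = np.tanh(params.w_out @ h + params.b_o)
    return h, y


def run_episode(
    params: RNNParams,
    episode: Episode,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one episode from the zero hidden state; return (trace [4x16], y_final [8])."""
    h = np.zeros(N_HIDDEN)
    trace = np.zeros((episode.frames.shape[0], N_HIDDEN))
    y = np.zeros(N_OUT)
    for t in range(episode.frames.shape[0]):
        h, y = step(params, h, episode.frames[t], noise=noise, rng=rng)
        trace[t] = h
    return trace, y


def run_batch(
    params: RNNParams,
    frames: np.ndarray,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run all episodes in one vectorised pass.

    frames: [n, T, 4].  Returns (states [n, T, 16], outputs [n, 8]); each
    episode starts from the zero hidden state and draws its own noise
    offsets at every update.
    """
    n, n_t, _ = frames.shape
    h = np.zeros((n, N_HIDDEN))
    states = np.zeros((n, n_t, N_HIDDEN))
    noisy = noise is not None and noise.r > 0 and len(noise.targets) > 0
    if noisy and rng is None:
        raise ValueError("a NoiseSpec with r > 0 requires an rng")
    for t in range(n_t):
        if noisy:
            mt = _noisy_m_batch(params.m, noise, n, rng)
            rec = np.einsum("nij,nj->ni", mt, h)
        else:
            rec = h @ params.m.T
        h = np.tanh(frames[:, t, :] @ params.w_in.T + rec + params.b_h)
        states[:, t, :] = h
    y = np.tanh(h @ params.w_out.T + params.b_o)
    return states, y


def classify(y_final: np.ndarray) -> int:
    """Readout: index of the maximal output, ties broken toward the lowest index."""
    y_final = np.asarray(y_final)
    if not np.all(np.isfinite(y_final)):
        raise ValueError("non-finite outputs")
    return int(np.argmax(y_final))


def evaluate(
    params: RNNParams,
    data: EpisodeSet,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> PerformanceRecord:
    """Score the network on the episode set (E, w, a, W as in the module docstring)."""
    if data.n == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    _, outputs = run_batch(params, data.frames, noise=noise, rng=rng)
    targets = target_matrix(data)
    d = outputs - targets
    e = float(np.sum(d * d))
    w = 1.0 - e / (data.n * data.m)
    a = int(np.sum(np.argmax(outputs, axis=1) == data.labels))
    fitness = float(1.5 ** (w * a))
    return PerformanceRecord(e=e, w=w, a=a, fitness=fitness)


def record_traces(params: RNNParams, data: EpisodeSet) -> StateTrace:
    """Noise-free hidden-state recording over the full episode set."""
    states, _ = run_batch(params, data.frames)
    return StateTrace(states=states)
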