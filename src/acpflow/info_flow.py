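"""Set-wise transfer entropy on median-binarized recurrent-state traces.

Each hidden node's continuous activation series (96 samples: 24 episodes x
4 timesteps) is thresholded at its own median — values strictly above the
median become 1, everything else 0 — which maximises the marginal entropy
of each binary variable.  Transfer entropy from a source node set S to a
single target node j is the plug-in conditional mutual information

    TE_{S->j} = I(X^j_{t+1} ; X^S_t | X^j_t)
              = H(X^j_{t+1}, X^j_t) + H(X^j_t, X^S_t)
                - H(X^j_t) - H(X^j_{t+1}, X^j_t, X^S_t)

estimated from the empirical distribution over the 72 within-episode
state transitions (t -> t+1 for t = 0, 1, 2; transitions never span
episodes and the pre-episode zero state is excluded).  Dynamics are
treated as Markovian: only the most recent state conditions the future.

Source and target must be disjoint and the source set nonempty; the
target is always a single node.  The plug-in estimator carries a positive
small-sample bias, characterised (not corrected) by the property suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elman_rnn import N_HIDDEN, StateTrace


@dataclass(frozen=True)
class SourceTargetPair:
    """A nonempty source node set and a disjoint single target node."""

    sources: tuple[int, ...]
    target: int

    def __post_init__(self) -> None:
        sources = tuple(sorted(set(int(s) for s in self.sources)))
        object.__setattr__(self, "sources", sources)
        if not sources:
            raise ValueError("source set must be nonempty")
        if self.target in sources:
            raise ValueError("source set and target must be disjoint")
        if not all(0 <= s < N_HIDDEN for s in sources) or not 0 <= self.target < N_HIDDEN:
            raise ValueError(f"node indices must lie in 0..{N_HIDDEN - 1}")

    @property
    def size(self) -> int:
        return len(self.sources)


@dataclass(frozen=True)
class TERecord:
    """Transfer entropy of one (source set, target) draw, with per-node value."""

    network_id: str
    pair: SourceTargetPair
    te_bits: float

    @property
    def te_per_node(self) -> float:
        return self.te_bits / self.pair.size


@dataclass
class BinaryTrace:
    """Median-binarized recurrent states with within-episode transitions."""

    bits: np.ndarray       # [n_episodes, T, 16], uint8
    medians: np.ndarray    # [16]
    degenerate: np.ndarray  # [16] bool: node had a constant series

    @property
    def transitions(self) -> tuple[np.ndarray, np.ndarray]:
        frm = self.bits[:, :-1, :].reshape(-1, N_HIDDEN)
        to = self.bits[:, 1:, :].reshape(-1, N_HIDDEN)
        return frm, to


def binarize(trace: StateTrace) -> BinaryTrace:
    """Threshold each node at its pooled median (strictly above -> 1).

    The median is taken per node over all recorded states (episodes and
    timesteps pooled).  Values equal to the median map to 0, so a constant
    (degenerate) node yields an all-zero series, which is flagged.
    """
    states = trace.states
    if states.shape[0] * states.shape[1] < 2:
        raise ValueError("need at least 2 samples per node to binarize")
    flat = states.reshape(-1, states.shape[2])
    medians = np.median(flat, axis=0)
    bits = (states > medians).astype(np.uint8)
    degenerate = np.ptp(flat, axis=0) == 0
    return BinaryTrace(bits=bits, medians=medians, degenerate=degenerate)


def joint_distribution(bt: BinaryTrace, pair: SourceTargetPair) -> np.ndarray:
    """Empirical p(x^j_{t+1}, x^j_t, x^S_t), shape [2, 2, 2^|S|].

    The last axis indexes the joint source state, encoded as a binary
    number with pair.sources[0] as the least significant bit.
    """
    frm, to = bt.transitions
    k = pair.size
    src_code = frm[:, list(pair.sources)].astype(np.int64) @ (1 << np.arange(k))
    j_now = frm[:, pair.target].astype(np.int64)
    j_next = to[:, pair.target].astype(np.int64)
    table = np.zeros((2, 2, 1 << k))
    np.add.at(table, (j_next, j_now, src_code), 1.0)
    return table / table.sum()


def transfer_entropy(table: np.ndarray) -> float:
    """Plug-in TE (bits) from a p(x^j_{t+1}, x^j_t, x^S_t) table.

    Evaluated termwise as p * log2[ p(x'|x_j, x_S) / p(x'|x_j) ] with the
    0 log 0 = 0 convention.  Raises if the table is not normalised.
    """
    table = np.asarray(table, dtype=float)
    if abs(table.sum() - 1.0) > 1e-9:
        raise ValueError("probability table is not normalised")
    p_js = table.sum(axis=0, keepdims=True)        # p(x_j, x_S)
    p_nj = table.sum(axis=2, keepdims=True)        # p(x', x_j)
    p_j = table.sum(axis=(0, 2), keepdims=True)    # p(x_j)
    mask = table > 0
    te = np.sum(
        table[mask]
        * np.log2((table[mask] * p_j.repeat(2, 0).repeat(table.shape[2], 2)[mask])
                  / (p_js.repeat(2, 0)[mask] * p_nj.repeat(table.shape[2], 2)[mask]))
    )
    # clip tiny negative rounding residue; plug-in TE is nonnegative
    return float(max(te, 0.0))


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Empirical Shannon entropy (bits) of an integer-coded sample."""
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def te_from_bits(bt: BinaryTrace, pair: SourceTargetPair) -> float:
    """TE via the entropy decomposition; fast path used by the profile scan.

    Numerically identical (to rounding) to ``transfer_entropy`` applied to
    ``joint_distribution`` — the oracle tests hold both routes together.
    """
    frm, to = bt.transitions
    k = pair.size
    src = frm[:, list(pair.sources)].astype(np.int64) @ (1 << np.arange(k))
    j_now = frm[:, pair.target].astype(np.int64)
    j_next = to[:, pair.target].astype(np.int64)
    h_j = _entropy_from_codes(j_now)
    h_nj = _entropy_from_codes(j_next * 2 + j_now)
    h_js = _entropy_from_codes(j_now * (1 << k) + src)
    h_njs = _entropy_from_codes((j_next * 2 + j_now) * (1 << k) + src)
    return float(max(h_nj + h_js - h_j - h_njs, 0.0))


def sample_pairs(
    set_size: int, count: int, rng: np.random.Generator
) -> list[SourceTargetPair]:
    """Uniform random (source set, target) draws among the 16 hidden nodes.

    The source set is drawn uniformly without replacement; the target
    uniformly from the remaining nodes.  Duplicate pairs across draws are
    permitted (sampling with replacement over the pair space).
    """
    if not 1 <= set_size <= N_HIDDEN - 1:
        raise ValueError(f"set_size must be in 1..{N_HIDDEN - 1}")
    pairs = []
    for _ in range(count):
        nodes = rng.choice(N_HIDDEN, size=set_size + 1, replace=False)
        pairs.append(SourceTargetPair(sources=tuple(nodes[:-1]), target=int(nodes[-1])))
    return pairs


def te_profile(
    trace: StateTrace,
    sizes: Iterable[int] = range(1, N_HIDDEN),
    count_per_size: int = 100,
    rng: np.random.Generator | None = None,
    network_id: str = "",
) -> list[TERecord]:
    """Binarize once, then TE over random source sets of each requested size.

    Records keep their (S, j) pair so the perturbation analysis can be run
    on the identical draws.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    bt = binarize(trace)
    records = []
    for size in sizes:
        for pair in sample_pairs(size, count_per_size, rng):
            records.append(
                TERecord(network_id=network_id, pair=pair, te_bits=te_from_bits(bt, pair))
            )
    return records


def records_to_frame(records: Sequence[TERecord], method: str = "", seed: int | None = None) -> pd.DataFrame:
    """Delimited-text-ready table of TE records."""
    return pd.DataFrame(
        {
            "network_id": [r.network_id for r in records],
            "method": method,
            "set_size": [r.pair.size for r in records],
            "source_nodes": [";".join(map(str, r.pair.sources)) for r in records],
            "target_node": [r.pair.target for r in records],
            "te_bits": [r.te_bits for r in records],
            "te_per_node": [r.te_per_node for r in records],
            "seed": seed,
        }
    )
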