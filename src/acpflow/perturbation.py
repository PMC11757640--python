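"""Lesion-style weight importance via one-sided uniform noise sweeps.

A weight (or weight group) of the recurrent matrix M is perturbed by
adding a fresh draw from U[0, r] at every computational update, and the
network's normalised fitness w under perturbation is compared to its
unperturbed fitness w0.  Sweeping the upper bound r over 21 levels from
0.0 to 4.0 (step 0.2) and averaging the relative performance
W_bar = <w~ / w0> over levels and repeats yields the importance

    I = 1 - W_bar

which is ~0 for functionally irrelevant weights and approaches 1 when
perturbation destroys performance.  For a group of weights (all edges
from a source set S into a target node j, i.e. row j, columns S of M)
every targeted weight experiences the same noise regime; draws are
independent per weight per update by default (a shared-draw variant is
available through ``NoiseSpec.sharing``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acp_task import EpisodeSet
from .elman_rnn import N_HIDDEN, NoiseSpec, RNNParams, evaluate
from .info_flow import SourceTargetPair


@dataclass
class NoiseSweep:
    """21 uniform noise levels r = 0.0, 0.2, ..., 4.0; ``repeats`` evaluations each."""

    levels: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 4.0, 21))
    repeats: int = 10

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels[0] != 0.0:
            raise ValueError("first noise level must be exactly 0 (no perturbation)")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("noise levels must be strictly increasing")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ImportanceRecord:
    """Noise-sweep outcome for one targeted weight group."""

    network_id: str
    targets: tuple[tuple[int, int], ...]
    levels: np.ndarray
    mean_rel_perf_per_level: np.ndarray
    pair: SourceTargetPair | None = None

    @property
    def mean_rel_perf(self) -> float:
        """Scalar W_bar: uniform average over all levels (and repeats)."""
        return float(np.mean(self.mean_rel_perf_per_level))

    @property
    def importance(self) -> float:
        return 1.0 - self.mean_rel_perf


def _unperturbed_fitness(params: RNNParams, data: EpisodeSet) -> float:
    w0 = evaluate(params, data).w
    if w0 <= 0:
        raise ValueError(
            f"unperturbed fitness w0={w0:.4f} is not positive; "
            "relative performance is undefined for this network"
        )
    return w0


def perturbed_performance(
    params: RNNParams,
    targets: Iterable[tuple[int, int]],
    r: float,
    repeats: int,
    data: EpisodeSet,
    rng: np.random.Generator,
    sharing: str = "independent",
    w0: float | None = None,
) -> float:
    """Mean relative performance <w~ / w0> at one noise bound r.

    Each repeat is a full evaluation over all episodes with fresh U[0, r]
    offsets on the targeted M entries at every update.
    """
    targets = tuple(targets)
    if w0 is None:
        w0 = _unperturbed_fitness(params, data)
    if r == 0 or not targets:
        return 1.0
    spec = NoiseSpec(targets=targets, r=float(r), sharing=sharing)
    ratios = [evaluate(params, data, noise=spec, rng=rng).w / w0 for _ in range(repeats)]
    return float(np.mean(ratios))


def importance(
    params: RNNParams,
    targets: Iterable[tuple[int, int]],
    sweep: NoiseSweep,
    data: EpisodeSet,
    rng: np.random.Generator,
    network_id: str = "",
    sharing: str = "independent",
    pair: SourceTargetPair | None = None,
) -> ImportanceRecord:
    """Full noise sweep over the targeted weight group."""
    targets = tuple(targets)
    w0 = _unperturbed_fitness(params, data)
    per_level = np.array(
        [
            perturbed_performance(
                params, targets, r, sweep.repeats, data, rng, sharing=sharing, w0=w0
            )
            for r in sweep.levels
        ]
    )
    return ImportanceRecord(
        network_id=network_id,
        targets=targets,
        levels=sweep.levels.copy(),
        mean_rel_perf_per_level=per_level,
        pair=pair,
    )


def importance_matrix(
    params: RNNParams,
    sweep: NoiseSweep,
    data: EpisodeSet,
    rng: np.random.Generator,
    network_id: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Single-weight importance for every entry of M.

    Returns (I [16 x 16], curves [16 x 16 x n_levels]); entry (i, j) is
    the importance of the recurrent weight M[i, j] (edge j -> i).
    """
    n_levels = len(sweep.levels)
    imat = np.zeros((N_HIDDEN, N_HIDDEN))
    curves = np.zeros((N_HIDDEN, N_HIDDEN, n_levels))
    _unperturbed_fitness(params, data)  # fail fast on degenerate networks
    for i in range(N_HIDDEN):
        for j in range(N_HIDDEN):
            rec = importance(
                params, [(i, j)], sweep, data, rng, network_id=network_id
            )
            imat[i, j] = rec.importance
            curves[i, j] = rec.mean_rel_perf_per_level
    return imat, curves


def targets_for_pair(pair: SourceTargetPair) -> tuple[tuple[int, int], ...]:
    """M entries carrying the edges S -> j: row j (target), columns S (sources)."""
    return tuple((pair.target, s) for s in pair.sources)


def set_importance_for_pairs(
    params: RNNParams,
    pairs: Sequence[SourceTargetPair],
    sweep: NoiseSweep,
    data: EpisodeSet,
    rng: np.random.Generator,
    network_id: str = "",
    sharing: str = "independent",
) -> list[ImportanceRecord]:
    """Group importance for each (S, j) draw, aligned one-to-one with ``pairs``.

    Designed to run on the same pairs used for the TE profile so that
    transfer entropy and importance are paired observations.
    """
    return [
        importance(
            params,
            targets_for_pair(pair),
            sweep,
            data,
            rng,
            network_id=network_id,
            sharing=sharing,
            pair=pair,
        )
        for pair in pairs
    ]


def records_to_frame(
    records: Sequence[ImportanceRecord], method: str = "", seed: int | None = None
) -> pd.DataFrame:
    """Summary table (one row per record); see also ``curves_to_frame``."""
    rows = []
    for r in records:
        if r.pair is not None:
            set_size = r.pair.size
            source_nodes = ";".join(map(str, r.pair.sources))
            target_node = r.pair.target
        else:
            set_size = len(r.targets)
            source_nodes = ";".join(str(c) for _, c in r.targets)
            target_node = r.targets[0][0] if r.targets else -1
        rows.append(
            {
                "network_id": r.network_id,
                "method": method,
                "set_size": set_size,
                "source_nodes": source_nodes,
                "target_node": target_node,
                "mean_rel_perf": r.mean_rel_perf,
                "importance": r.importance,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def curves_to_frame(
    records: Sequence[ImportanceRecord], method: str = "", seed: int | None = None
) -> pd.DataFrame:
    """Long-format per-level relative-performance curves."""
    rows = []
    for rec_id, r in enumerate(records):
        for lvl, perf in zip(r.levels, r.mean_rel_perf_per_level):
            rows.append(
                {
                    "network_id": r.network_id,
                    "method": method,
                    "record": rec_id,
                    "noise_bound": lvl,
                    "mean_rel_perf": perf,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
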