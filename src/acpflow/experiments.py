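"""Replicate orchestration and the headline analyses.

Trains independent replicates by GA and by backpropagation until perfect
classification, then, on the perfect networks only:

* a paired TE/importance scan over random source sets of sizes 1..15
  (identical (S, j) draws feed both measures),
* per-size Spearman rank correlations between TE and importance,
* mean importance, TE and TE-per-node curves versus set size, with the
  per-method argmax of information per source node,
* pooled recurrent-weight distribution comparison between methods
  (two-sample Kolmogorov-Smirnov).

Two scale profiles are provided: ``desk`` (10 replicates per method, 30
subsets per size, 5 noise repeats — minutes on one CPU) and ``paper``
(50 / 100 / 10).  All randomness flows from a single master seed through
documented per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acp_task import EpisodeSet, generate_dataset
from .elman_rnn import RNNParams, evaluate, record_traces
from .info_flow import binarize, sample_pairs, te_from_bits
from .perturbation import NoiseSweep, set_importance_for_pairs
from .trainers import BPConfig, GAConfig, TrainingHistory, evolve, train_bp

PROFILES = {
    "desk": {"n_replicates": 10, "count_per_size": 100, "repeats": 5},
    "paper": {"n_replicates": 50, "count_per_size": 100, "repeats": 10},
}


def replication_config(method: str) -> "GAConfig | BPConfig":
    """Training configuration of the replication experiments.

    Networks are Xavier-seeded and trained until the first perfect
    classifier appears.  GA: population 100, per-weight mutation
    probability 0.01, mutation variance 0.1, roulette-wheel selection,
    cap 2000 generations.  BP: full-batch gradient descent, cap 5000
    epochs.  See docs/methods.md for the rationale behind the seeding and
    stopping conventions.
    """
    if method == "GA":
        return GAConfig(init_scheme="xavier", stop_at_perfect=True, max_generations=2000)
    if method == "BP":
        return BPConfig(init_scheme="xavier", stop_at_perfect=True, max_epochs=5000)
    raise ValueError("method must be 'GA' or 'BP'")


@dataclass
class Replicate:
    seed: int
    params: RNNParams
    history: TrainingHistory
    perfect: bool
    first_perfect: int | None


@dataclass
class ReplicateArchive:
    """Terminal networks and histories of one method's replicate runs."""

    method: str  # "GA" or "BP"
    replicates: list[Replicate] = field(default_factory=list)

    @property
    def perfect(self) -> list[Replicate]:
        return [r for r in self.replicates if r.perfect]

    def __len__(self) -> int:
        return len(self.replicates)


def run_replicates(
    method: str,
    n_replicates: int,
    base_seed: int,
    config: GAConfig | BPConfig | None = None,
    data: EpisodeSet | None = None,
) -> ReplicateArchive:
    """Train n replicates with seeds base_seed .. base_seed + n - 1.

    Replicates that never reach perfect classification within their budget
    are archived but flagged; only perfect networks enter later analyses.
    Every archived perfect network is re-evaluated as a consistency check.
    """
    if method not in ("GA", "BP"):
        raise ValueError("method must be 'GA' or 'BP'")
    if data is None:
        data = generate_dataset()
    archive = ReplicateArchive(method=method)
    for k in range(n_replicates):
        seed = base_seed + k
        if method == "GA":
            cfg = GAConfig(**{**_cfg_kwargs(config), "seed": seed})
            params, history = evolve(cfg, data)
        else:
            cfg = BPConfig(**{**_cfg_kwargs(config), "seed": seed})
            params, history = train_bp(cfg, data)
        # the perfect flag is grounded in re-evaluation of the archived
        # network itself, not the training log: only networks that classify
        # all episodes correctly right now enter the analyses
        perfect = evaluate(params, data).a == data.n
        if perfect and history.first_perfect is None:
            raise RuntimeError(
                f"{method} replicate seed={seed}: perfect network but no "
                "perfect iteration recorded"
            )
        archive.replicates.append(
            Replicate(
                seed=seed,
                params=params,
                history=history,
                perfect=perfect,
                first_perfect=history.first_perfect,
            )
        )
    return archive


def _cfg_kwargs(config) -> dict:
    if config is None:
        return {}
    return {k: v for k, v in vars(config).items()}


def te_importance_scan(
    archive: ReplicateArchive,
    data: EpisodeSet,
    sizes: Sequence[int] = range(1, 16),
    count_per_size: int = 100,
    sweep: NoiseSweep | None = None,
    seed: int = 0,
    with_importance: bool = True,
) -> pd.DataFrame:
    """Paired TE / importance table over identical (S, j) draws.

    For every perfect network and every set size, ``count_per_size`` random
    (source set, target) pairs are drawn; each pair feeds both the plug-in
    set transfer entropy and (optionally) the noise-sweep importance, so
    every row is a paired observation.
    """
    if not archive.perfect:
        raise ValueError(f"archive for {archive.method} contains no perfect network")
    if sweep is None:
        sweep = NoiseSweep()
    rows = []
    for rep in archive.perfect:
        net_id = f"{archive.method}-{rep.seed}"
        rng = np.random.default_rng((seed, rep.seed, 1))
        bt = binarize(record_traces(rep.params, data))
        for size in sizes:
            pairs = sample_pairs(size, count_per_size, rng)
            te_vals = [te_from_bits(bt, p) for p in pairs]
            if with_importance:
                irecs = set_importance_for_pairs(
                    rep.params, pairs, sweep, data, rng, network_id=net_id
                )
                imp_vals = [ir.importance for ir in irecs]
                rel_vals = [ir.mean_rel_perf for ir in irecs]
            else:
                imp_vals = [np.nan] * len(pairs)
                rel_vals = [np.nan] * len(pairs)
            for pair, te, imp, rel in zip(pairs, te_vals, imp_vals, rel_vals):
                rows.append(
                    {
                        "network_id": net_id,
                        "method": archive.method,
                        "set_size": size,
                        "source_nodes": ";".join(map(str, pair.sources)),
                        "target_node": pair.target,
                        "te_bits": te,
                        "te_per_node": te / size,
                        "mean_rel_perf": rel,
                        "importance": imp,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def correlation_by_size(paired: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Spearman rank correlation of TE vs importance per set size.

    Observations are pooled across networks within each (method, size).
    Degenerate (constant) columns yield NaN correlation, reported as such.
    A Bonferroni-adjusted p column (15 sizes) is added for transparency.
    """
    out = []
    for (method, size), grp in paired.groupby(["method", "set_size"]):
        x = grp["importance"].to_numpy()
        y = grp["te_bits"].to_numpy()
        if len(grp) < 3:
            raise ValueError("need >= 3 paired observations per size")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
        out.append(
            {
                "method": method,
                "set_size": size,
                "n": len(grp),
                "spearman_rho": rho,
                "p_value": p,
                "p_bonferroni": min(p * 15, 1.0) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(out)


def set_size_curves(paired: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mean +/- standard error of importance, TE and TE/|S| per (method, size).

    Also returns, per method, the set size at which mean TE per source node
    peaks — the per-connection information maximum.
    """
    rows = []
    argmax: dict[str, int] = {}
    for method, mgrp in paired.groupby("method"):
        means = mgrp.groupby("set_size").agg(
            mean_importance=("importance", "mean"),
            sem_importance=("importance", "sem"),
            mean_te=("te_bits", "mean"),
            sem_te=("te_bits", "sem"),
            mean_te_per_node=("te_per_node", "mean"),
            sem_te_per_node=("te_per_node", "sem"),
            n=("te_bits", "size"),
        )
        argmax[method] = int(means["mean_te_per_node"].idxmax())
        means = means.reset_index()
        means.insert(0, "method", method)
        rows.append(means)
    return pd.concat(rows, ignore_index=True), argmax


def pooled_recurrent_weights(archive: ReplicateArchive, include_all: bool = False) -> np.ndarray:
    """Recurrent-matrix weights of all perfect networks, pooled.

    With ``include_all`` every parameter (input, recurrent, output weights
    and biases) is pooled instead of M only.
    """
    if include_all:
        return np.concatenate([r.params.to_vector() for r in archive.perfect])
    return np.concatenate([r.params.m.ravel() for r in archive.perfect])


def weight_distribution_report(
    ga_archive: ReplicateArchive,
    bp_archive: ReplicateArchive,
    bins: int = 60,
    include_all: bool = False,
) -> dict:
    """Compare terminal recurrent-weight distributions between methods.

    Returns pooled samples, a shared-bin histogram per method, per-network
    rank-sorted weight curves, and the two-sample Kolmogorov-Smirnov
    statistic and p-value between the pooled GA and BP samples.
    """
    ga_w = pooled_recurrent_weights(ga_archive, include_all)
    bp_w = pooled_recurrent_weights(bp_archive, include_all)
    if ga_w.size == 0 or bp_w.size == 0:
        raise ValueError("need at least one perfect network per method")
    lo = min(ga_w.min(), bp_w.min())
    hi = max(ga_w.max(), bp_w.max())
    edges = np.linspace(lo, hi, bins + 1)
    ks = stats.ks_2samp(ga_w, bp_w)
    return {
        "ga_weights": ga_w,
        "bp_weights": bp_w,
        "bin_edges": edges,
        "ga_hist": np.histogram(ga_w, bins=edges, density=True)[0],
        "bp_hist": np.histogram(bp_w, bins=edges, density=True)[0],
        "ga_rank_curves": np.stack(
            [np.sort(r.params.m.ravel()) for r in ga_archive.perfect]
        ),
        "bp_rank_curves": np.stack(
            [np.sort(r.params.m.ravel()) for r in bp_archive.perfect]
        ),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
    }


def build_report(
    out_dir: str | Path,
    paired: pd.DataFrame,
    correlations: pd.DataFrame,
    curves: pd.DataFrame,
    argmax: dict[str, int],
    weight_report: dict | None = None,
    histories: dict[str, list[TrainingHistory]] | None = None,
    manifest: dict | None = None,
) -> Path:
    """Render figures and write every backing table as delimited text.

    Produces a TE-vs-importance scatter grid per method, importance / TE /
    TE-per-node curves versus set size, and (when a weight report is given)
    pooled weight histograms and rank-sorted weight curves; the manifest
    (configs, seeds, sizes) is written as JSON so a report can be
    regenerated deterministically.
    """
    import json

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if paired.empty:
        raise ValueError("cannot build a report from an empty paired table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paired.to_csv(out / "te_importance_pairs.tsv", sep="\t", index=False)
    correlations.to_csv(out / "correlation_by_size.tsv", sep="\t", index=False)
    curves.to_csv(out / "set_size_curves.tsv", sep="\t", index=False)

    # scatter grids (one per method, one panel per set size)
    for method, mgrp in paired.groupby("method"):
        fig, axes = plt.subplots(4, 4, figsize=(12, 12), sharex=False)
        for ax, size in zip(axes.ravel(), range(1, 16)):
            sgrp = mgrp[mgrp["set_size"] == size]
            ax.scatter(sgrp["mean_rel_perf"], sgrp["te_bits"], s=4, alpha=0.4)
            ax.axhline(sgrp["te_bits"].mean(), color="red", ls=":", lw=0.8)
            ax.axvline(sgrp["mean_rel_perf"].mean(), color="red", ls=":", lw=0.8)
            ax.set_title(f"|S| = {size}", fontsize=8)
        cax = axes.ravel()[15]
        sub = correlations[correlations["method"] == method]
        cax.plot(sub["set_size"], sub["p_value"], "r.-", label="p")
        cax.plot(sub["set_size"], sub["spearman_rho"], "k.-", label="rho")
        cax.legend(fontsize=6)
        cax.set_title("Spearman", fontsize=8)
        fig.suptitle(f"TE vs relative performance ({method})")
        fig.tight_layout()
        fig.savefig(out / f"scatter_{method.lower()}.png", dpi=120)
        plt.close(fig)

    # set-size curves
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    colors = {"GA": "black", "BP": "red"}
    for method, mgrp in curves.groupby("method"):
        c = colors.get(method, None)
        for ax, (mean_col, sem_col, title) in zip(
            axes,
            [
                ("mean_importance", "sem_importance", "importance"),
                ("mean_te", "sem_te", "TE (bits)"),
                ("mean_te_per_node", "sem_te_per_node", "TE per source node (bits)"),
            ],
        ):
            ax.plot(mgrp["set_size"], mgrp[mean_col], color=c, label=method)
            ax.fill_between(
                mgrp["set_size"],
                mgrp[mean_col] - mgrp[sem_col],
                mgrp[mean_col] + mgrp[sem_col],
                color=c,
                alpha=0.25,
            )
            ax.set_xlabel("|S|")
            ax.set_title(title)
    for ax in axes:
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "set_size_curves.png", dpi=120)
    plt.close(fig)

    if weight_report is not None:
        centers = 0.5 * (weight_report["bin_edges"][:-1] + weight_report["bin_edges"][1:])
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        ax1.plot(centers, weight_report["ga_hist"], color="black", label="GA")
        ax1.plot(centers, weight_report["bp_hist"], color="red", label="BP")
        ax1.set_xlabel("recurrent weight")
        ax1.set_ylabel("density")
        ax1.legend()
        for curve in weight_report["ga_rank_curves"]:
            ax2.plot(curve, color="black", lw=0.5, alpha=0.5)
        for curve in weight_report["bp_rank_curves"]:
            ax2.plot(curve, color="red", lw=0.5, alpha=0.5)
        ax2.set_xlabel("rank")
        ax2.set_ylabel("weight")
        fig.tight_layout()
        fig.savefig(out / "weight_distributions.png", dpi=120)
        plt.close(fig)
        pd.DataFrame(
            {
                "bin_center": centers,
                "ga_density": weight_report["ga_hist"],
                "bp_density": weight_report["bp_hist"],
            }
        ).to_csv(out / "weight_histogram.tsv", sep="\t", index=False)

    if histories:
        fig, axes = plt.subplots(1, len(histories), figsize=(5 * len(histories), 4))
        axes = np.atleast_1d(axes)
        for ax, (method, hists) in zip(axes, histories.items()):
            for h in hists:
                for gen, m in h.snapshots:
                    ax.scatter([gen] * m.size, m.ravel(), s=1, alpha=0.2, color="gray")
            ax.set_title(f"M trajectory ({method})")
            ax.set_xlabel("iteration")
            ax.set_ylabel("weight")
        fig.tight_layout()
        fig.savefig(out / "weight_trajectories.png", dpi=120)
        plt.close(fig)

    full_manifest = {"argmax_te_per_node": argmax}
    if weight_report is not None:
        full_manifest["ks_statistic"] = weight_report["ks_statistic"]
        full_manifest["ks_p_value"] = weight_report["ks_p_value"]
    if manifest:
        full_manifest.update(manifest)
    (out / "manifest.json").write_text(json.dumps(full_manifest, indent=2, default=str))
    return out
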