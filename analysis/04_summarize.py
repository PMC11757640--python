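"""Headline analyses: correlations, set-size curves, weight distributions.

Consumes the paired scan of 03 and the networks of 02 and reproduces the
study's summary results:

* Spearman rank correlation between transfer entropy and importance for
  every source-set size (the study's central negative result: no size
  shows a significant positive correlation),
* mean importance, TE, and TE per source node versus set size, with the
  per-method argmax of information density (GA peaks at size 3, BP at 2),
* pooled recurrent-weight histograms, per-network rank-sorted weight
  curves, and the two-sample Kolmogorov-Smirnov comparison of the GA and
  BP weight distributions.
"""

import argparse
import re
from pathlib import Path

import pandas as pd

from acpflow.elman_rnn import RNNParams, evaluate
from acpflow.acp_task import generate_dataset
from acpflow.experiments import (
    Replicate,
    ReplicateArchive,
    build_report,
    correlation_by_size,
    set_size_curves,
    weight_distribution_report,
)


def load_archives(net_dir: Path, data) -> dict[str, ReplicateArchive]:
    archives = {m: ReplicateArchive(method=m) for m in ("GA", "BP")}
    for path in sorted(net_dir.glob("*.txt")):
        method, seed = re.match(r"(GA|BP)_(\d+)", path.stem).groups()
        params = RNNParams.load_text(path)
        perfect = evaluate(params, data).a == data.n
        archives[method].replicates.append(
            Replicate(seed=int(seed), params=params, history=None,
                      perfect=perfect, first_perfect=None)
        )
    return archives


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    paired = pd.read_csv(args.out / "te_importance_pairs.tsv", sep="\t")
    data = generate_dataset()
    archives = load_archives(args.out / "networks", data)

    correlations = correlation_by_size(paired.dropna(subset=["importance"]))
    curves, argmax = set_size_curves(paired)
    weights = weight_distribution_report(archives["GA"], archives["BP"])
    out = build_report(
        args.out / "report", paired, correlations, curves, argmax, weights,
        manifest={"n_networks": {m: len(a.perfect) for m, a in archives.items()}},
    )

    print("per-connection information peak (argmax of mean TE/|S|):", argmax)
    sig = correlations[correlations.p_value < 0.05]
    print(f"sizes with significant TE-importance correlation (raw p<0.05): "
          f"{len(sig)} of {len(correlations)}")
    print(f"recurrent-weight KS statistic {weights['ks_statistic']:.4f}, "
          f"p = {weights['ks_p_value']:.4g}")
    print(f"report written to {out}/")


if __name__ == "__main__":
    main()
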