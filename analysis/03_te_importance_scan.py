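"""Paired transfer-entropy / importance scan over random source sets.

For every perfect network archived by 02_train_replicates.py: record the
hidden states over all 24 episodes, binarize them at per-node medians,
draw random (source set, target) pairs for every set size 1-15, and
compute for each draw both the plug-in set transfer entropy and the
noise-sweep importance of the corresponding recurrent weights — the same
draws feed both measures, so every row of the output is a paired
observation.
"""

import argparse
import re
from pathlib import Path

import numpy as np
import pandas as pd

from acpflow.acp_task import generate_dataset
from acpflow.elman_rnn import RNNParams, record_traces
from acpflow.info_flow import binarize, sample_pairs, te_from_bits
from acpflow.perturbation import NoiseSweep, set_importance_for_pairs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--count-per-size", type=int, default=30,
                    help="random (S, j) draws per set size per network")
    ap.add_argument("--repeats", type=int, default=5,
                    help="noisy evaluations per noise level")
    ap.add_argument("--skip-importance", action="store_true",
                    help="TE only (much faster)")
    args = ap.parse_args()

    data = generate_dataset()
    sweep = NoiseSweep(repeats=args.repeats)
    net_dir = args.out / "networks"
    paths = sorted(net_dir.glob("*.txt"))
    if not paths:
        raise SystemExit(f"no networks found under {net_dir}; run 02_train_replicates.py first")

    rows = []
    for path in paths:
        method, seed = re.match(r"(GA|BP)_(\d+)", path.stem).groups()
        params = RNNParams.load_text(path)
        rng = np.random.default_rng((args.seed, int(seed)))
        bt = binarize(record_traces(params, data))
        for size in range(1, 16):
            pairs = sample_pairs(size, args.count_per_size, rng)
            te = [te_from_bits(bt, p) for p in pairs]
            if args.skip_importance:
                imp = rel = [np.nan] * len(pairs)
            else:
                recs = set_importance_for_pairs(params, pairs, sweep, data, rng)
                imp = [r.importance for r in recs]
                rel = [r.mean_rel_perf for r in recs]
            for p, t, i, w in zip(pairs, te, imp, rel):
                rows.append(
                    {
                        "network_id": path.stem,
                        "method": method,
                        "set_size": size,
                        "source_nodes": ";".join(map(str, p.sources)),
                        "target_node": p.target,
                        "te_bits": t,
                        "te_per_node": t / size,
                        "mean_rel_perf": w,
                        "importance": i,
                        "seed": args.seed,
                    }
                )
        print(f"scanned {path.stem}", flush=True)

    table = pd.DataFrame(rows)
    out_path = args.out / "te_importance_pairs.tsv"
    table.to_csv(out_path, sep="\t", index=False)
    print(f"wrote {out_path}: {len(table)} paired observations "
          f"({table.network_id.nunique()} networks x 15 sizes x {args.count_per_size} draws)")


if __name__ == "__main__":
    main()
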