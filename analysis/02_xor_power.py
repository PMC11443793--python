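#!/usr/bin/env python
"""Clean-XOR power study: ten methods across interaction orders 2-5.

Runs the weakest-link evaluation on the full clean XOR grid (orders 2-5,
20-100 total features, 1600 instances) at a scaled-down replicate count and
reports where Relief-based detection collapses.  Writes the tidy record
table, per-configuration heatmap matrices (TSV), and heatmap images.
"""

import argparse
import pathlib
import sys

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import rbabench as rb  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20250924)
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--orders", default="2,3,4,5")
    ap.add_argument("--features", default="20,40,60,80,100")
    args = ap.parse_args()

    orders = [int(x) for x in args.orders.split(",")]
    feats = [int(x) for x in args.features.split(",")]
    configs = [c for c in rb.xor_grid() if c.order in orders and c.n_total in feats]
    records = rb.run_experiment_grid(
        configs, seed_base=args.seed, replicates=args.replicates
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    records.to_csv(results / "xor_weakest_links.tsv", sep="\t", index=False)

    figdir = ROOT / "scratch" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for config in configs:
        curves = rb.power_table(records, config.config_id)
        tsv = None
        if config.n_total == 100:  # keep the headline panels as text
            tsv = results / f"xor_power_{config.config_id}.tsv"
        rb.render_heatmap(
            curves, png_path=figdir / f"{config.config_id}.png", tsv_path=tsv
        )

    # narrative: success = all predictive features in the top n_predictive ranks
    print(f"{len(configs)} configs x {args.replicates} replicates x 10 methods")
    print("power (%) at position = #predictive, by order (n=100 features):")
    for order in orders:
        cid = f"xor_k{order}_n100_m1600"
        if cid not in set(records["config_id"]):
            continue
        curves = rb.power_table(records, cid)
        at_k = curves.iloc[:, order - 1]
        tops = ", ".join(f"{mth}={val:.0f}" for mth, val in at_k.items())
        print(f"  {order}-way: {tops}")
    print(f"records -> {results / 'xor_weakest_links.tsv'}")


if __name__ == "__main__":
    main()
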