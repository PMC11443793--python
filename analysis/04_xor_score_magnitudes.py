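#!/usr/bin/env python
"""Why more neighbors do not rescue absolute-value ranking at high order.

Averages |ReliefF score| over predictive and non-predictive features of
clean 4-way and 5-way XOR datasets at 10 vs 100 nearest neighbors.  With
100 neighbors the non-predictive weights shrink toward zero — but so do the
predictive ones, so the separation absolute-value ranking relies on shrinks
too.  Writes results/xor_score_magnitudes.json.
"""

import argparse
import json
import pathlib
import sys

ROOT = pathlib.Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from rbabench.magnitudes import xor_score_magnitudes  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20250924)
    ap.add_argument("--replicates", type=int, default=5)
    args = ap.parse_args()

    res = xor_score_magnitudes(seed_base=args.seed, replicates=args.replicates)
    out = ROOT / "results" / "xor_score_magnitudes.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(res, indent=2) + "\n")

    print(f"{res['n_datasets']} clean 4-/5-way XOR datasets, 1600 instances each")
    for cls in ("nonpredictive", "predictive"):
        a10, a100 = res[f"{cls}_10nn"], res[f"{cls}_100nn"]
        print(f"  {cls:14s} mean|score|: 10NN={a10:.4f}  100NN={a100:.4f}")
    sep10 = res["predictive_10nn"] / res["nonpredictive_10nn"]
    sep100 = res["predictive_100nn"] / res["nonpredictive_100nn"]
    print(
        f"  predictive/non-predictive separation: 10NN={sep10:.2f}x, "
        f"100NN={sep100:.2f}x -> more neighbors shrink both feature classes"
    )
    print(f"results -> {out}")


if __name__ == "__main__":
    main()
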