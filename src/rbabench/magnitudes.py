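"""Average absolute ReliefF score magnitudes on higher-order XOR data.

In clean 4-way and 5-way XOR data the interesting quantity is not the rank
but the magnitude of the weights themselves: with many neighbors the
positive and negative updates of non-predictive features cancel toward
zero, but so do those of the predictive features, which is why more
neighbors do not rescue absolute-value ranking at high interaction orders.
This module computes those averages over the high-order XOR grid.
"""

from __future__ import annotations

import numpy as np

from .relief import pairwise_distance, relieff_scores_multi
from .simulate import derive_seed, make_xor_dataset

__all__ = ["xor_score_magnitudes"]


def xor_score_magnitudes(
    seed_base: int,
    orders=(4, 5),
    feature_counts=(20, 40, 60, 80, 100),
    m: int = 1600,
    replicates: int = 5,
    nns=(10, 100),
) -> dict:
    """Mean |ReliefF score| for predictive and non-predictive features.

    Generates clean XOR datasets for every (order, feature count, replicate)
    cell, scores each once per NN setting (sharing the distance matrix), and
    averages absolute scores separately over predictive and non-predictive
    columns across all datasets.

    Returns
    -------
    dict
        ``{"predictive_<nn>nn": float, "nonpredictive_<nn>nn": float, ...}``
        plus ``"n_datasets"``.
    """
    nns = sorted(set(int(v) for v in nns))
    sums = {("pred", nn): 0.0 for nn in nns} | {("nonpred", nn): 0.0 for nn in nns}
    counts = {("pred", nn): 0 for nn in nns} | {("nonpred", nn): 0 for nn in nns}
    n_datasets = 0
    for order in orders:
        for n_total in feature_counts:
            for r in range(replicates):
                seed = derive_seed(seed_base, "xormag", order, n_total, r)
                rng = np.random.default_rng(seed)
                ds = make_xor_dataset(order, n_total, m, rng, replicate_seed=seed)
                D = pairwise_distance(ds)
                scored = relieff_scores_multi(ds, nns, D=D)
                pred = np.array(ds.predictive_idx)
                mask = np.zeros(n_total, dtype=bool)
                mask[pred] = True
                for nn in nns:
                    a = np.abs(scored[nn].scores)
                    sums[("pred", nn)] += a[mask].sum()
                    counts[("pred", nn)] += int(mask.sum())
                    sums[("nonpred", nn)] += a[~mask].sum()
                    counts[("nonpred", nn)] += int((~mask).sum())
                n_datasets += 1
    out = {"n_datasets": n_datasets}
    for nn in nns:
        out[f"predictive_{nn}nn"] = sums[("pred", nn)] / counts[("pred", nn)]
        out[f"nonpredictive_{nn}nn"] = sums[("nonpred", nn)] / counts[("nonpred", nn)]
    return out
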