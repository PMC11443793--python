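"""Ranking schemes, weakest-link power evaluation and reporting.

The evaluation asks one question of every method: after scoring a dataset,
where does the *worst-ranked* known predictive feature land?  That position
is the "weakest link" — missing even one feature of a k-way interaction
breaks downstream modeling, so only the weakest link counts.  Across
replicates the per-position success percentages form a power curve, and the
curves for all ten methods (four Relief-based scorers under standard and
absolute-value ranking, plus the random-shuffle and mutual-information
controls) are reported as a heatmap row each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import comb

from .controls import mutual_info_scores, shuffle_ranking
from .errors import IntegrityError, InvalidParameterError
from .relief import (
    DEFAULT_DEADBAND,
    multisurf_scores,
    multisurfstar_scores,
    pairwise_distance,
    relieff_scores_multi,
)
from .simulate import derive_seed, generate_dataset

__all__ = [
    "METHOD_ORDER",
    "rank_features",
    "weakest_link_rank",
    "power_curve",
    "analytic_shuffle_curve",
    "score_all_methods",
    "run_experiment_grid",
    "power_table",
    "render_heatmap",
]

# Fixed reporting order: standard RBA rankings, absolute-value rankings,
# then the two controls.
METHOD_ORDER = (
    "ReliefF-10NN",
    "ReliefF-100NN",
    "MultiSURF",
    "MultiSURF*",
    "ReliefF-10NN_ABS",
    "ReliefF-100NN_ABS",
    "MultiSURF_ABS",
    "MultiSURF*_ABS",
    "Shuffle",
    "MutualInformation",
)

_RBA_BASE = {
    "ReliefF-10NN": ("relieff", 10),
    "ReliefF-100NN": ("relieff", 100),
    "MultiSURF": ("multisurf", None),
    "MultiSURF*": ("multisurfstar", None),
}


def rank_features(scores, scheme: str = "standard") -> np.ndarray:
    """Order features best-first under a ranking scheme.

    standard: descending raw score (most positive first).
    absolute: descending absolute score, so strongly negative weights rank
    alongside strongly positive ones.  Ties break by ascending feature index.
    """
    raw = np.asarray(getattr(scores, "scores", scores), dtype=float)
    if not np.isfinite(raw).all():
        raise InvalidParameterError("scores must be finite")
    if scheme == "standard":
        key = raw
    elif scheme == "absolute":
        key = np.abs(raw)
    else:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    # lexsort: primary descending key, secondary ascending index
    return np.lexsort((np.arange(key.size), -key))


def weakest_link_rank(ordering, predictive_idx) -> int:
    """1-based rank of the worst-ranked predictive feature."""
    ordering = np.asarray(ordering)
    positions = {int(f): p + 1 for p, f in enumerate(ordering)}
    try:
        return max(positions[int(i)] for i in predictive_idx)
    except KeyError as exc:
        raise IntegrityError(f"predictive feature {exc} missing from ordering")


def weakest_link_pessimistic(scores, predictive_idx, scheme: str = "standard") -> int:
    """Worst-case weakest link if every score tie resolved against us.

    A feature's pessimistic rank is the number of features whose ranking key
    is >= its own (all tied features placed ahead of it).
    """
    raw = np.asarray(getattr(scores, "scores", scores), dtype=float)
    key = np.abs(raw) if scheme == "absolute" else raw
    return int(max((key >= key[int(i)]).sum() for i in predictive_idx))


def power_curve(weakest_links, n: int) -> np.ndarray:
    """Per-position success percentages over replicates.

    Entry p (1-based position) is the percentage of replicates whose weakest
    link ranked at or better than p; the curve is non-decreasing and ends
    at 100.
    """
    wl = np.asarray(weakest_links, dtype=int)
    if wl.size < 1:
        raise InvalidParameterError("need at least one replicate")
    if (wl < 1).any() or (wl > n).any():
        raise InvalidParameterError("weakest links must lie in [1, n]")
    positions = np.arange(1, n + 1)
    return 100.0 * (wl[None, :] <= positions[:, None]).mean(axis=1)


def analytic_shuffle_curve(n: int, n_predictive: int) -> np.ndarray:
    """Exact power curve of a uniformly random feature ordering.

    The weakest link of q predictive features under a random permutation of
    n is the maximum of q uniform draws without replacement, so
    P(weakest <= p) = C(p, q) / C(n, q).
    """
    q = n_predictive
    p = np.arange(1, n + 1)
    return 100.0 * comb(p, q) / comb(n, q)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def score_all_methods(
    dataset,
    methods=METHOD_ORDER,
    deadband_multiplier: float = DEFAULT_DEADBAND,
    shuffle_seed: int = 0,
) -> dict:
    """Run every requested method on one dataset.

    Returns ``{method_label: ordering (best-first ndarray)}`` with the
    expensive pieces shared: one distance matrix serves all Relief scorers
    and each scorer runs once for its standard and absolute rankings.
    """
    methods = list(methods)
    base_needed = {}
    for label in methods:
        base = label[:-4] if label.endswith("_ABS") else label
        if base in _RBA_BASE:
            base_needed[base] = _RBA_BASE[base]
        elif base not in ("Shuffle", "MutualInformation"):
            raise InvalidParameterError(f"unknown method {label!r}")

    raw_scores = {}
    if base_needed:
        D = pairwise_distance(dataset)
        nns = sorted({nn for alg, nn in base_needed.values() if alg == "relieff"})
        if nns:
            multi = relieff_scores_multi(dataset, nns, D=D)
        for base, (alg, nn) in base_needed.items():
            if alg == "relieff":
                raw_scores[base] = multi[nn].scores
            elif alg == "multisurf":
                raw_scores[base] = multisurf_scores(
                    dataset, deadband_multiplier, D=D
                ).scores
            else:
                raw_scores[base] = multisurfstar_scores(
                    dataset, deadband_multiplier, D=D
                ).scores

    orderings = {}
    for label in methods:
        if label == "Shuffle":
            rng = np.random.default_rng(shuffle_seed)
            orderings[label] = shuffle_ranking(dataset, rng).permutation
        elif label == "MutualInformation":
            orderings[label] = rank_features(
                mutual_info_scores(dataset).scores, "standard"
            )
        elif label.endswith("_ABS"):
            orderings[label] = rank_features(raw_scores[label[:-4]], "absolute")
        else:
            orderings[label] = rank_features(raw_scores[label], "standard")
    return orderings


def run_experiment_grid(
    configs,
    seed_base: int,
    methods=METHOD_ORDER,
    replicates: int = None,
    deadband_multiplier: float = DEFAULT_DEADBAND,
) -> pd.DataFrame:
    """Weakest-link records for every config x replicate x method.

    ``replicates`` overrides each config's own replicate count (the scaling
    knob).  Fully reproducible: dataset and shuffle seeds derive from
    ``seed_base`` and the config id.

    Returns a tidy frame with columns config_id, replicate, replicate_seed,
    method, scheme, weakest_link, n_features, rows in the fixed method order.
    """
    if not list(methods):
        raise InvalidParameterError("methods must be nonempty")
    records = []
    for config in configs:
        reps = replicates if replicates is not None else config.replicates
        for r in range(reps):
            ds = generate_dataset(config, r, seed_base)
            orderings = score_all_methods(
                ds,
                methods=methods,
                deadband_multiplier=deadband_multiplier,
                shuffle_seed=derive_seed(seed_base, config.config_id, r, "shuffle"),
            )
            for label in methods:
                if label not in orderings:
                    raise IntegrityError(f"no scores produced for method {label!r}")
                wl = weakest_link_rank(orderings[label], ds.predictive_idx)
                records.append(
                    {
                        "config_id": config.config_id,
                        "replicate": r,
                        "replicate_seed": ds.replicate_seed,
                        "method": label,
                        "scheme": "absolute" if label.endswith("_ABS") else "standard",
                        "weakest_link": wl,
                        "n_features": ds.n_features,
                    }
                )
    return pd.DataFrame.from_records(records)


def power_table(records: pd.DataFrame, config_id: str) -> pd.DataFrame:
    """Power curves for one config: rows = methods, columns = positions."""
    sub = records[records["config_id"] == config_id]
    if sub.empty:
        raise InvalidParameterError(f"no records for config {config_id!r}")
    n = int(sub["n_features"].iloc[0])
    if (sub["n_features"] != n).any():
        raise InvalidParameterError("inconsistent n_features within config")
    rows = {}
    for label in METHOD_ORDER:
        wl = sub.loc[sub["method"] == label, "weakest_link"]
        if wl.empty:
            continue
        rows[label] = power_curve(wl.to_numpy(), n)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=np.arange(1, n + 1)
    )


def render_heatmap(curves: pd.DataFrame, png_path=None, tsv_path=None):
    """Write a power heatmap (one row per method) and its exact TSV matrix.

    Low percentages render orange-to-white, high percentages blue.  The TSV
    carries the numeric matrix at full precision; the image is presentation
    only.
    """
    if curves.ndim != 2 or curves.shape[1] < 1:
        raise InvalidParameterError("curves must be a methods x positions matrix")
    if tsv_path is not None:
        curves.to_csv(tsv_path, sep="\t", index_label="method")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap

        cmap = LinearSegmentedColormap.from_list(
            "power", ["#e66101", "#ffffff", "#0571b0"]
        )
        fig, ax = plt.subplots(
            figsize=(max(6, curves.shape[1] / 12), 0.4 * curves.shape[0] + 1.5)
        )
        im = ax.imshow(curves.to_numpy(), cmap=cmap, vmin=0, vmax=100, aspect="auto")
        ax.set_yticks(range(curves.shape[0]), curves.index)
        ax.set_xlabel("ranking position")
        fig.colorbar(im, ax=ax, label="% of replicates with weakest link at or above")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return curves
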