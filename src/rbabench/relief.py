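"""Relief-based feature weighting over discrete genotype data.

Implements ReliefF (fixed neighbor count), MultiSURF (adaptive near-neighbor
threshold) and MultiSURF* (near plus inverse-scored far instances) for
binary-outcome datasets of {0,1,2} genotypes.  The distance between two
instances is the number of features at which their genotypes differ
(Hamming; equivalent to Manhattan on this encoding with a 0/1 per-feature
diff).  All instances serve once as the scoring target and every weight
lands in [-1, 1].

The per-feature weight semantics are the classic Relief ones: differences
at a feature between the target and an opposite-class neighbor (a "miss")
push the weight up, differences with a same-class neighbor (a "hit") push it
down, so features that separate the classes locally score positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateClassError, InvalidParameterError

__all__ = [
    "ScoringConfig",
    "NeighborPartition",
    "ScoreVector",
    "pairwise_distance",
    "relieff_scores",
    "relieff_scores_multi",
    "multisurf_partition",
    "multisurf_scores",
    "multisurfstar_scores",
]

DEFAULT_DEADBAND = 0.5


@dataclass
class ScoringConfig:
    """Run parameters for one scorer."""

    algorithm: str  # relieff | multisurf | multisurfstar
    nn: int = 10  # ReliefF neighbor count (the NN run parameter)
    deadband_multiplier: float = DEFAULT_DEADBAND

    def __post_init__(self):
        if self.algorithm not in ("relieff", "multisurf", "multisurfstar"):
            raise InvalidParameterError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "relieff" and self.nn < 1:
            raise InvalidParameterError("nn must be >= 1")
        if self.deadband_multiplier < 0:
            raise InvalidParameterError("deadband_multiplier must be >= 0")


@dataclass
class NeighborPartition:
    """Near/far split of the other instances around one target."""

    target_index: int
    threshold: float  # mean distance from target to all others
    deadband: float  # multiplier x std of those distances
    near_set: np.ndarray  # indices with d < threshold - deadband
    far_set: np.ndarray  # indices with d > threshold + deadband


@dataclass
class ScoreVector:
    """Per-feature weights from one scorer on one dataset."""

    scores: np.ndarray
    algorithm: str
    config_id: str = ""
    replicate_seed: int = 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


def _as_arrays(dataset):
    X = np.asarray(dataset.genotypes)
    y = np.asarray(dataset.labels)
    return X, y


def _check_classes(y, min_count: int = 2):
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) < 2 or counts.min() < min_count:
        raise DegenerateClassError(
            f"need >= {min_count} instances of each class, got {dict(zip(vals.tolist(), counts.tolist()))}"
        )


def pairwise_distance(dataset) -> np.ndarray:
    """Full m x m genotype-mismatch (Hamming) distance matrix.

    Computed as n minus the match count via one-hot inner products, which
    keeps the cost at one (m x 3n)(3n x m) matrix product instead of an
    m^2 n comparison sweep.  Entries are exact integers.
    """
    X, _ = _as_arrays(dataset)
    m, n = X.shape
    if m < 2:
        raise InvalidParameterError("need at least 2 instances")
    onehot = np.concatenate([(X == v) for v in (0, 1, 2)], axis=1).astype(np.float32)
    matches = onehot @ onehot.T
    D = np.rint(n - matches).astype(np.int64)
    np.fill_diagonal(D, 0)
    return D


def _same_value_weighted(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """For each (target t, feature f): sum_j W[t, j] * [X[j, f] == X[t, f]].

    Three matrix products (one per genotype value) replace the cubic loop.
    """
    out = np.zeros((W.shape[0], X.shape[1]), dtype=np.float64)
    for v in (0, 1, 2):
        ov = (X == v).astype(np.float64)
        out += (W @ ov) * ov
    return out


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def relieff_scores_multi(dataset, nns, D: np.ndarray = None) -> dict:
    """Score a dataset with ReliefF at several NN settings at once.

    The distance matrix and the per-target stable neighbor orderings are
    shared between settings, so scoring at 10 and 100 neighbors costs barely
    more than one setting.  Returns ``{nn: ScoreVector}``.

    For each target the ``nn`` nearest same-class instances (hits) and
    opposite-class instances (misses) are selected (ties broken by ascending
    instance index); each feature's weight accumulates
    ``(miss diffs - hit diffs) / (m * nn)``.  If a target has fewer than
    ``nn`` hits or misses available, all available are used (one warning per
    dataset) and that side is normalized by its own count.
    """
    X, y = _as_arrays(dataset)
    m, n = X.shape
    _check_classes(y)
    nns = sorted(set(int(v) for v in nns))
    if nns[0] < 1:
        raise InvalidParameterError("nn must be >= 1")
    if D is None:
        D = pairwise_distance(dataset)

    # lexicographic key: distance first, ascending instance index second
    key = D.astype(np.int64) * m + np.arange(m, dtype=np.int64)[None, :]
    big = np.iinfo(np.int64).max
    same = y[None, :] == y[:, None]
    np.fill_diagonal(same, False)
    opp = y[None, :] != y[:, None]

    hit_key = np.where(same, key, big)
    miss_key = np.where(opp, key, big)
    hit_order = np.argsort(hit_key, axis=1)
    miss_order = np.argsort(miss_key, axis=1)
    n_hits = same.sum(axis=1)
    n_miss = opp.sum(axis=1)

    results = {}
    warned = False
    for nn in nns:
        kh = np.minimum(nn, n_hits)
        km = np.minimum(nn, n_miss)
        if not warned and ((kh < nn).any() or (km < nn).any()):
            warnings.warn(
                f"{dataset.config_id or 'dataset'}: fewer than nn={nn} hits or "
                "misses for some targets; using all available",
                stacklevel=2,
            )
            warned = True
        rank = np.arange(m, dtype=np.int64)[None, :]
        Wh = np.zeros((m, m), dtype=np.float64)
        Wm = np.zeros((m, m), dtype=np.float64)
        np.put_along_axis(Wh, hit_order, (rank < kh[:, None]).astype(np.float64), axis=1)
        np.put_along_axis(Wm, miss_order, (rank < km[:, None]).astype(np.float64), axis=1)
        # mismatch sums: selected count minus same-genotype count
        hit_diff = kh[:, None] - _same_value_weighted(Wh, X)
        miss_diff = km[:, None] - _same_value_weighted(Wm, X)
        miss_term = np.divide(
            miss_diff, km[:, None], out=np.zeros_like(miss_diff), where=km[:, None] > 0
        )
        hit_term = np.divide(
            hit_diff, kh[:, None], out=np.zeros_like(hit_diff), where=kh[:, None] > 0
        )
        per_target = miss_term - hit_term
        scores = per_target.sum(axis=0) / m
        results[nn] = ScoreVector(
            scores=scores,
            algorithm=f"relieff_{nn}nn",
            config_id=dataset.config_id,
            replicate_seed=dataset.replicate_seed,
        )
    return results


def relieff_scores(dataset, nn: int = 10, D: np.ndarray = None) -> ScoreVector:
    """ReliefF feature weights with ``nn`` nearest hits and misses."""
    return relieff_scores_multi(dataset, [nn], D=D)[int(nn)]


# ---------------------------------------------------------------------------
# MultiSURF / MultiSURF*
# ---------------------------------------------------------------------------


def _thresholds(D: np.ndarray, deadband_multiplier: float):
    """Per-target mean distance T_i and dead-band D_i over the other rows."""
    m = D.shape[0]
    Df = D.astype(np.float64)
    row_sum = Df.sum(axis=1)  # diagonal is 0
    T = row_sum / (m - 1)
    sq_sum = (Df**2).sum(axis=1)
    var = sq_sum / (m - 1) - T**2
    sigma = np.sqrt(np.maximum(var, 0.0))
    return T, deadband_multiplier * sigma


def multisurf_partition(
    dataset, target: int, deadband_multiplier: float = DEFAULT_DEADBAND,
    D: np.ndarray = None,
) -> NeighborPartition:
    """Near/far partition of the other instances around one target.

    An instance j is near iff ``d(t, j) < T_i - D_i`` and far iff
    ``d(t, j) > T_i + D_i`` where T_i is the mean distance from the target
    to all other instances and D_i the dead-band (multiplier x std of those
    distances); instances inside the band are excluded as ambiguous.
    """
    X, _ = _as_arrays(dataset)
    m = X.shape[0]
    if m < 3:
        raise InvalidParameterError("need at least 3 instances")
    if D is None:
        D = pairwise_distance(dataset)
    d = D[target].astype(np.float64)
    others = np.arange(m) != target
    T = d[others].mean()
    sigma = d[others].std()
    band = deadband_multiplier * sigma
    near = np.flatnonzero(others & (d < T - band))
    far = np.flatnonzero(others & (d > T + band))
    return NeighborPartition(
        target_index=target, threshold=T, deadband=band, near_set=near, far_set=far
    )


def _surf_terms(D, X, y, deadband_multiplier):
    """Weighted mismatch terms for the four (zone, class) combinations.

    Each term[t, f] is the mean genotype mismatch between target t and its
    near/far hits/misses at feature f (0 where the set is empty).
    """
    m = X.shape[0]
    T, band = _thresholds(D, deadband_multiplier)
    Df = D.astype(np.float64)
    others = ~np.eye(m, dtype=bool)
    near = others & (Df < (T - band)[:, None])
    far = others & (Df > (T + band)[:, None])
    same = y[None, :] == y[:, None]

    terms = {}
    for zone_name, zone in (("near", near), ("far", far)):
        for cls_name, cls in (("hit", same), ("miss", ~same)):
            mask = (zone & cls).astype(np.float64)
            counts = mask.sum(axis=1)
            # integer-exact mismatch counts, normalized per target afterwards
            diff_counts = counts[:, None] - _same_value_weighted(mask, X)
            terms[(zone_name, cls_name)] = np.divide(
                diff_counts,
                counts[:, None],
                out=np.zeros_like(diff_counts),
                where=counts[:, None] > 0,
            )
    return terms


def multisurf_scores(
    dataset, deadband_multiplier: float = DEFAULT_DEADBAND, D: np.ndarray = None
) -> ScoreVector:
    """MultiSURF weights: near-zone scoring only.

    Per target, the mean mismatch over near misses minus the mean mismatch
    over near hits (each side normalized by its own member count; an empty
    side contributes nothing); summed over targets and divided by m.
    """
    X, y = _as_arrays(dataset)
    _check_classes(y)
    if X.shape[0] < 3:
        raise InvalidParameterError("need at least 3 instances")
    if D is None:
        D = pairwise_distance(dataset)
    t = _surf_terms(D, X, y, deadband_multiplier)
    per_target = t[("near", "miss")] - t[("near", "hit")]
    return ScoreVector(
        scores=per_target.sum(axis=0) / X.shape[0],
        algorithm="multisurf",
        config_id=dataset.config_id,
        replicate_seed=dataset.replicate_seed,
    )


def multisurfstar_scores(
    dataset, deadband_multiplier: float = DEFAULT_DEADBAND, D: np.ndarray = None
) -> ScoreVector:
    """MultiSURF* weights: near-zone scoring plus inverse-scored far zone.

    Far instances update with inverted sign (far-hit mismatches add, far-miss
    mismatches subtract), which is what gives the algorithm its power on pure
    pairwise interactions.  The per-target near and far contributions are
    averaged so weights stay in [-1, 1].
    """
    X, y = _as_arrays(dataset)
    _check_classes(y)
    if X.shape[0] < 3:
        raise InvalidParameterError("need at least 3 instances")
    if D is None:
        D = pairwise_distance(dataset)
    t = _surf_terms(D, X, y, deadband_multiplier)
    per_target = 0.5 * (
        t[("near", "miss")] - t[("near", "hit")]
        + t[("far", "hit")] - t[("far", "miss")]
    )
    return ScoreVector(
        scores=per_target.sum(axis=0) / X.shape[0],
        algorithm="multisurfstar",
        config_id=dataset.config_id,
        replicate_seed=dataset.replicate_seed,
    )
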