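"""Simulation of genotype datasets with known predictive architecture.

This module generates the full grid of study datasets: clean full-penetrance
XOR interactions of order 2-5, noisy pure/strict penetrance-table models
(2- and 3-way epistasis), univariate and additive non-epistatic models, and
heterogeneous two-subgroup mixtures.  Genotypes are minor-allele counts in
{0, 1, 2} sampled under Hardy-Weinberg equilibrium; the binary outcome is
drawn from a penetrance function of the predictive genotypes.

A penetrance model of order ``k`` assigns a case probability
``f(g_1, ..., g_k)`` to each of the ``3**k`` multi-locus genotypes.  The
population prevalence ``K`` is the genotype-probability-weighted mean of the
table and the (broad-sense) heritability is ``h2 = Var(f) / (K (1 - K))``.
"Pure, strict" models carry their entire signal in the full-order
interaction: marginalizing the table onto any proper subset of its loci
yields a constant penetrance, so no lower-order or univariate test can see
the effect.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FeasibilityError, FormatError, InvalidParameterError

__all__ = [
    "GenotypeDataset",
    "PenetranceModel",
    "ExperimentConfig",
    "hwe_probs",
    "sample_genotypes",
    "xor_penetrance_table",
    "make_xor_dataset",
    "make_penetrance_model",
    "verify_pure_strict",
    "assemble_dataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "derive_seed",
    "xor_grid",
    "table1_grid",
]

_PREDICTIVE_NAME = re.compile(r"^M\d+P\d+$")

# Non-predictive ("noise") loci draw their minor-allele frequency uniformly
# from this range, mirroring common GAMETES practice.
NOISE_MAF_RANGE = (0.05, 0.5)


def derive_seed(seed_base: int, *parts) -> int:
    """Derive a reproducible 31-bit seed from a base seed and context parts."""
    key = ":".join([str(seed_base), *map(str, parts)])
    digest = hashlib.blake2s(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """A genotype matrix with binary labels and known predictive columns.

    Attributes
    ----------
    genotypes : ndarray of shape (m, n)
        Minor-allele counts in {0, 1, 2}.
    labels : ndarray of shape (m,)
        Binary class labels in {0, 1}.
    predictive_idx : tuple of int
        Column indices of the ground-truth predictive features.
    feature_names : list of str
        Column names; predictive features follow the ``M<i>P<j>`` convention.
    replicate_seed : int
    config_id : str
    """

    genotypes: np.ndarray
    labels: np.ndarray
    predictive_idx: tuple
    feature_names: list
    replicate_seed: int = 0
    config_id: str = ""

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.predictive_idx = tuple(int(i) for i in self.predictive_idx)

    @property
    def n_instances(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_features(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        m, n = self.genotypes.shape
        if self.labels.shape != (m,):
            raise InvalidParameterError("labels length does not match genotypes")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise InvalidParameterError("genotype entries must be in {0,1,2}")
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidParameterError("labels must be in {0,1}")
        if not self.predictive_idx:
            raise InvalidParameterError("predictive_idx must be nonempty")
        if any(i < 0 or i >= n for i in self.predictive_idx):
            raise InvalidParameterError("predictive_idx out of range")
        if len(self.feature_names) != n:
            raise InvalidParameterError("feature_names length does not match")


@dataclass
class PenetranceModel:
    """A k-locus penetrance table with its generating parameters.

    ``table`` has shape ``(3,) * order`` and entry ``table[g1, ..., gk]`` is
    the probability of the case outcome given that multi-locus genotype.
    """

    order: int
    table: np.ndarray
    mafs: np.ndarray
    prevalence: float
    heritability: float
    difficulty: str = "n/a"

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.table.shape != (3,) * self.order:
            raise InvalidParameterError(
                f"table shape {self.table.shape} does not match order {self.order}"
            )
        if self.mafs.shape != (self.order,):
            raise InvalidParameterError("mafs length must equal order")
        if (self.table < 0).any() or (self.table > 1).any():
            raise InvalidParameterError("penetrance values must lie in [0,1]")

    def genotype_probs(self) -> np.ndarray:
        """Joint HWE genotype probabilities, shape ``(3,) * order``."""
        probs = hwe_probs(self.mafs[0])
        for maf in self.mafs[1:]:
            probs = np.multiply.outer(probs, hwe_probs(maf))
        return probs

    def realized_prevalence(self) -> float:
        """K recomputed from the table by direct weighted summation."""
        return float(np.sum(self.genotype_probs() * self.table))

    def realized_heritability(self) -> float:
        """h2 = Var(f) / (K(1-K)) recomputed from the table."""
        probs = self.genotype_probs()
        k = float(np.sum(probs * self.table))
        var = float(np.sum(probs * (self.table - k) ** 2))
        return var / (k * (1.0 - k))

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        """Evaluate the table at an (m, order) genotype matrix."""
        genotypes = np.asarray(genotypes)
        return self.table[tuple(genotypes[:, j] for j in range(self.order))]


@dataclass
class ExperimentConfig:
    """One cell of the simulation grid (a config-variation row)."""

    group: str
    order: int
    n_total: int
    n_predictive: int
    heritability: float
    m: int
    difficulty: str = "n/a"
    subgroup_ratio: tuple = None
    replicates: int = 30
    maf: float = 0.2
    prevalence: float = None  # None: prevalence floats during model search
    config_id: str = ""

    def __post_init__(self):
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        if not self.config_id:
            self.config_id = self._default_id()

    def _default_id(self) -> str:
        parts = [self.group, f"k{self.order}", f"n{self.n_total}", f"m{self.m}"]
        if self.heritability < 1:
            parts.append(f"h{self.heritability:g}")
        if self.difficulty in ("easy", "hard"):
            parts.append(self.difficulty)
        if self.subgroup_ratio is not None:
            parts.append("r" + "-".join(str(int(x)) for x in self.subgroup_ratio))
        return "_".join(parts)


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    maf = float(maf)
    if not (0.0 < maf <= 0.5):
        raise InvalidParameterError(f"maf must be in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def sample_genotypes(mafs, m: int, rng: np.random.Generator) -> np.ndarray:
    """Sample an (m, k) genotype matrix under HWE, one maf per column."""
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    if ((mafs <= 0.0) | (mafs > 0.5)).any():
        raise InvalidParameterError("every maf must be in (0, 0.5]")
    # inverse-CDF draw: P(0)=q^2, P(0 or 1)=q^2+2pq
    q = 1.0 - mafs
    c0 = q * q
    c1 = c0 + 2.0 * mafs * q
    u = rng.random((m, mafs.size))
    return ((u >= c0).astype(np.int8) + (u >= c1).astype(np.int8))


# ---------------------------------------------------------------------------
# XOR (parity) models — clean, full penetrance
# ---------------------------------------------------------------------------


def xor_penetrance_table(order: int) -> PenetranceModel:
    """The exact penetrance table implied by the parity construction.

    Each locus is binarized as 1 iff heterozygous; the outcome is the parity
    of the bits.  At maf 0.5 the heterozygote probability is exactly 1/2, so
    every proper-subset marginal penetrance is exactly 1/2 (pure and strict)
    and the table is deterministic (heritability 1).
    """
    if order not in (2, 3, 4, 5):
        raise InvalidParameterError(f"XOR order must be in 2..5, got {order}")
    grids = np.meshgrid(*[np.arange(3)] * order, indexing="ij")
    bits = sum((g == 1).astype(int) for g in grids)
    table = (bits % 2).astype(float)
    return PenetranceModel(
        order=order,
        table=table,
        mafs=np.full(order, 0.5),
        prevalence=0.5,
        heritability=1.0,
        difficulty="n/a",
    )


def make_xor_dataset(
    order: int,
    n_total: int,
    m: int,
    rng: np.random.Generator,
    config_id: str = "",
    replicate_seed: int = 0,
) -> GenotypeDataset:
    """Generate a clean n-way XOR dataset with full penetrance.

    The ``order`` predictive loci are sampled at maf 0.5, binarized by
    heterozygosity and the class is the parity (XOR) of the bits.  The
    remaining loci are independent maf-0.5 noise.
    """
    if order not in (2, 3, 4, 5):
        raise InvalidParameterError(f"XOR order must be in 2..5, got {order}")
    if n_total < order:
        raise InvalidParameterError("n_total must be >= order")
    genotypes = sample_genotypes(np.full(n_total, 0.5), m, rng)
    bits = (genotypes[:, :order] == 1).astype(np.int8)
    labels = bits.sum(axis=1) % 2
    names = [f"M0P{j}" for j in range(order)]
    names += [f"N{j}" for j in range(n_total - order)]
    ds = GenotypeDataset(
        genotypes=genotypes,
        labels=labels,
        predictive_idx=tuple(range(order)),
        feature_names=names,
        replicate_seed=replicate_seed,
        config_id=config_id or f"xor_k{order}_n{n_total}_m{m}",
    )
    return ds


# ---------------------------------------------------------------------------
# Noisy pure/strict penetrance models (GAMETES-style)
# ---------------------------------------------------------------------------


def _interaction_component(raw: np.ndarray, weights: list) -> np.ndarray:
    """Project a table onto the pure full-order interaction subspace.

    Subtracting the probability-weighted mean along each axis removes every
    lower-order component; what survives has all proper-subset marginals
    equal to zero.
    """
    out = raw.astype(float).copy()
    for axis, w in enumerate(weights):
        shape = [1] * out.ndim
        shape[axis] = 3
        mean = np.tensordot(out, w, axes=([axis], [0]))
        out = out - np.expand_dims(mean, axis)
    return out


def _detectability(model: PenetranceModel) -> float:
    """Shape statistic used to grade model difficulty.

    At fixed heritability the table variance is pinned, but how broadly the
    penetrance deviations are spread over common genotype cells still varies.
    Tables whose deviation mass sits on frequent genotypes are easier for
    neighbor-based scorers to pick up, so we score detectability as the
    probability-weighted mean absolute deviation relative to the standard
    deviation (maximal when the signal is spread evenly over common cells).
    """
    probs = model.genotype_probs()
    k = float(np.sum(probs * model.table))
    dev = model.table - k
    sd = np.sqrt(np.sum(probs * dev**2))
    if sd == 0:
        return 0.0
    return float(np.sum(probs * np.abs(dev)) / sd)


def make_penetrance_model(
    order: int,
    heritability: float,
    prevalence: float = None,
    mafs=0.2,
    difficulty: str = "n/a",
    rng: np.random.Generator = None,
    max_attempts: int = 500_000,
    population: int = 50,
) -> PenetranceModel:
    """Generate a random penetrance table at a requested heritability.

    Candidate tables are sampled (deviations biased toward common genotype
    cells), projected onto the constant-sub-marginal (pure/strict) subspace
    for ``order >= 2`` (centered for order 1), and rescaled so the table
    variance hits the requested heritability exactly; candidates that leave
    [0, 1] are rejected.  For ``difficulty`` "easy"/"hard" a population of
    valid models is generated and one is drawn from the top/bottom decile of
    a detectability score.

    ``prevalence`` may be fixed, but by default K floats: each candidate
    draws its own K and the returned model records the realized value.
    Pinning K severely tightens the feasible heritability range (at maf 0.2
    and K = 0.5 no pure/strict 2-way table exceeds h2 of about 0.32, and no
    3-way table about 0.18), so a free K is what makes the study's h2 = 0.4
    settings reachable — while 3-way tables above h2 of about 0.3 remain
    infeasible at any K.

    Raises
    ------
    FeasibilityError
        If too few valid tables are found within ``max_attempts`` candidates.
    """
    if order not in (1, 2, 3):
        raise InvalidParameterError(f"order must be in {{1,2,3}}, got {order}")
    if not (0.0 < heritability < 1.0):
        raise InvalidParameterError("heritability must be in (0, 1)")
    if prevalence is not None and not (0.0 < prevalence < 1.0):
        raise InvalidParameterError("prevalence must be in (0, 1)")
    if difficulty not in ("easy", "hard", "n/a"):
        raise InvalidParameterError(f"unknown difficulty {difficulty!r}")
    if rng is None:
        rng = np.random.default_rng()

    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (order,)).copy()
    weights = [hwe_probs(maf) for maf in mafs]
    probs = weights[0]
    for w in weights[1:]:
        probs = np.multiply.outer(probs, w)
    # sqrt-probability bias: rare cells get smaller raw deviations, which is
    # where nearly all of the feasible volume lives at higher heritability
    bias = np.sqrt(probs)

    n_needed = population if difficulty in ("easy", "hard") else 1
    found = []
    attempts = 0
    while len(found) < n_needed and attempts < max_attempts:
        attempts += 1
        k = prevalence if prevalence is not None else float(rng.uniform(0.05, 0.95))
        raw = rng.standard_normal((3,) * order) * bias
        dev = _interaction_component(raw, weights)
        var = float(np.sum(probs * dev**2))
        if var < 1e-12:
            continue
        dev *= np.sqrt(heritability * k * (1.0 - k) / var)
        table = k + dev
        if table.min() < 0.0 or table.max() > 1.0:
            continue
        found.append(
            PenetranceModel(
                order=order,
                table=table,
                mafs=mafs,
                prevalence=k,
                heritability=heritability,
                difficulty=difficulty,
            )
        )
    if len(found) < n_needed:
        raise FeasibilityError(
            f"no valid penetrance table for order={order}, h2={heritability}, "
            f"K={prevalence}, mafs={mafs.tolist()} after {attempts} attempts "
            f"({len(found)}/{n_needed} found)",
            attempts=attempts,
        )
    if difficulty == "n/a":
        return found[0]
    scored = sorted(found, key=_detectability)
    n_decile = max(1, len(scored) // 10)
    pool = scored[-n_decile:] if difficulty == "easy" else scored[:n_decile]
    return pool[int(rng.integers(len(pool)))]


def verify_pure_strict(model: PenetranceModel, tol: float = 1e-9):
    """Check that every proper-subset marginal penetrance is constant.

    For each nonempty proper subset S of loci the table is marginalized onto
    S by weighting the complementary loci with their HWE probabilities.  The
    model is pure/strict iff every such marginal is constant.

    Returns
    -------
    (bool, float)
        Whether all marginals are constant within ``tol``, and the maximum
        max-min deviation found across subsets.
    """
    if model.order < 2:
        raise InvalidParameterError("pure/strict check requires order >= 2")
    weights = [hwe_probs(maf) for maf in model.mafs]
    max_dev = 0.0
    axes = range(model.order)
    for r in range(1, model.order):
        for subset in itertools.combinations(axes, r):
            marg = model.table
            # contract complementary axes (descending so indices stay valid)
            for axis in sorted(set(axes) - set(subset), reverse=True):
                marg = np.tensordot(marg, weights[axis], axes=([axis], [0]))
            dev = float(marg.max() - marg.min())
            max_dev = max(max_dev, dev)
    return max_dev <= tol, max_dev


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _noise_block(n_noise: int, m: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = NOISE_MAF_RANGE
    mafs = rng.uniform(lo, hi, size=n_noise)
    if n_noise == 0:
        return np.empty((m, 0), dtype=np.int8)
    return sample_genotypes(mafs, m, rng)


def assemble_dataset(
    config: ExperimentConfig,
    models,
    rng: np.random.Generator,
    replicate_seed: int = 0,
) -> GenotypeDataset:
    """Assemble a dataset for one grid configuration.

    Homogeneous groups draw labels Bernoulli(f(predictive genotypes)) from a
    single model.  Heterogeneous groups split the instances by the subgroup
    ratio, label each subgroup with its own model and carry the other model's
    loci as non-predictive for that subgroup.  Additive groups sum per-locus
    penetrance deviations from K and clip to [0, 1].  Rows are shuffled so
    subgroup membership is not positional.
    """
    if config.group == "xor":
        return make_xor_dataset(
            config.order,
            config.n_total,
            config.m,
            rng,
            config_id=config.config_id,
            replicate_seed=replicate_seed,
        )

    models = list(models)
    m, n = config.m, config.n_total

    if config.group in ("hetero2way",):
        if config.subgroup_ratio is None:
            raise InvalidParameterError("heterogeneous config requires subgroup_ratio")
        ratio = np.asarray(config.subgroup_ratio, dtype=float)
        if abs(ratio.sum() - 100.0) > 1e-9:
            raise InvalidParameterError("subgroup_ratio must sum to 100")
        if len(models) != 2:
            raise InvalidParameterError("heterogeneous assembly needs two models")
        sizes = [int(round(m * ratio[0] / 100.0))]
        sizes.append(m - sizes[0])
        labels = np.empty(m, dtype=np.int8)
        names = []
        blocks = []
        for i, model in enumerate(models):
            blocks.append(sample_genotypes(model.mafs, m, rng))
            names += [f"M{i}P{j}" for j in range(model.order)]
        start = 0
        for i, (model, size) in enumerate(zip(models, sizes)):
            rows = slice(start, start + size)
            f = models[i].penetrance(blocks[i][rows])
            labels[rows] = (rng.random(size) < f).astype(np.int8)
            start += size
        pred = np.hstack(blocks)
        n_pred = pred.shape[1]
    elif config.group in ("additive2", "additive4"):
        if any(mod.order != 1 for mod in models):
            raise InvalidParameterError("additive assembly needs order-1 models")
        blocks = [sample_genotypes(mod.mafs, m, rng) for mod in models]
        k0 = models[0].prevalence
        f = np.full(m, k0)
        for mod, block in zip(models, blocks):
            f = f + (mod.table[block[:, 0]] - mod.prevalence)
        f = np.clip(f, 0.0, 1.0)
        labels = (rng.random(m) < f).astype(np.int8)
        pred = np.hstack(blocks)
        n_pred = pred.shape[1]
        names = [f"M{i}P0" for i in range(len(models))]
    else:  # homogeneous single-model groups
        if len(models) != 1:
            raise InvalidParameterError("homogeneous assembly needs one model")
        model = models[0]
        pred = sample_genotypes(model.mafs, m, rng)
        f = model.penetrance(pred)
        labels = (rng.random(m) < f).astype(np.int8)
        n_pred = model.order
        names = [f"M0P{j}" for j in range(model.order)]

    if n_pred != config.n_predictive:
        raise InvalidParameterError(
            f"models provide {n_pred} predictive loci, config wants {config.n_predictive}"
        )
    noise = _noise_block(n - n_pred, m, rng)
    genotypes = np.hstack([pred, noise])
    names = names + [f"N{j}" for j in range(n - n_pred)]
    perm = rng.permutation(m)
    ds = GenotypeDataset(
        genotypes=genotypes[perm],
        labels=labels[perm],
        predictive_idx=tuple(range(n_pred)),
        feature_names=names,
        replicate_seed=replicate_seed,
        config_id=config.config_id,
    )
    return ds


def _models_for_config(config: ExperimentConfig, seed_base: int):
    """Build the penetrance model(s) for a config, seeded independently of
    the replicate stream so all replicates share one model architecture."""
    rng = np.random.default_rng(derive_seed(seed_base, config.config_id, "model"))
    g = config.group
    if g == "xor":
        return []
    if g == "hetero2way":
        return [
            make_penetrance_model(
                2, config.heritability, config.prevalence, config.maf,
                config.difficulty, rng,
            )
            for _ in range(2)
        ]
    if g in ("additive2", "additive4"):
        n_loci = config.n_predictive
        shares = None
        if config.subgroup_ratio is not None:
            shares = np.asarray(config.subgroup_ratio, dtype=float) / 100.0
        else:
            shares = np.full(n_loci, 1.0 / n_loci)
        # per-locus h2 so the (pre-clipping) variance of the sum hits the target
        return [
            make_penetrance_model(
                1, config.heritability * share, config.prevalence, config.maf,
                "n/a", rng,
            )
            for share in shares
        ]
    order = config.order
    return [
        make_penetrance_model(
            order, config.heritability, config.prevalence, config.maf,
            config.difficulty, rng,
        )
    ]


def generate_dataset(
    config: ExperimentConfig, replicate: int, seed_base: int
) -> GenotypeDataset:
    """Generate one fully reproducible replicate of a grid configuration."""
    seed = derive_seed(seed_base, config.config_id, replicate)
    rng = np.random.default_rng(seed)
    models = _models_for_config(config, seed_base)
    return assemble_dataset(config, models, rng, replicate_seed=seed)


# ---------------------------------------------------------------------------
# Experiment grids
# ---------------------------------------------------------------------------

XOR_ORDERS = (2, 3, 4, 5)
XOR_FEATURE_COUNTS = (20, 40, 60, 80, 100)


def xor_grid(m: int = 1600, replicates: int = 30):
    """All clean XOR configurations: 4 orders x 5 feature counts = 20."""
    return [
        ExperimentConfig(
            group="xor", order=k, n_total=n, n_predictive=k,
            heritability=1.0, m=m, replicates=replicates,
        )
        for k in XOR_ORDERS
        for n in XOR_FEATURE_COUNTS
    ]


def table1_grid(replicates: int = 30, full_scale: bool = False):
    """The complete simulation grid, one ExperimentConfig per variation.

    With ``full_scale`` False the 100,000-feature configuration runs at
    10,000 features (its config id records the scaling).
    """
    configs = list(xor_grid(replicates=replicates))
    # core noisy 2-way: h2 x difficulty x instances
    for h2 in (0.05, 0.1, 0.2, 0.4):
        for diff in ("easy", "hard"):
            for m in (200, 400, 800, 1600):
                configs.append(
                    ExperimentConfig(
                        group="core2way", order=2, n_total=100, n_predictive=2,
                        heritability=h2, m=m, difficulty=diff,
                        replicates=replicates,
                    )
                )
    # feature-count scaling, h2=0.4 easy (100-feature point shared with core)
    for n in (1000, 10_000, 100_000):
        n_run = n if (full_scale or n <= 10_000) else 10_000
        cid = f"featurescale_k2_n{n}_m1600_h0.4_easy"
        if n_run != n:
            cid += "_scaled"
        configs.append(
            ExperimentConfig(
                group="featurescale", order=2, n_total=n_run, n_predictive=2,
                heritability=0.4, m=1600, difficulty="easy",
                replicates=replicates, config_id=cid,
            )
        )
    # heterogeneous pairs of independent 2-way models
    for ratio in ((50, 50), (75, 25)):
        configs.append(
            ExperimentConfig(
                group="hetero2way", order=2, n_total=100, n_predictive=4,
                heritability=0.4, m=1600, difficulty="easy",
                subgroup_ratio=ratio, replicates=replicates,
            )
        )
    # noisy 3-way (h2 0.2: higher is infeasible for pure/strict 3-way tables)
    configs.append(
        ExperimentConfig(
            group="epi3way", order=3, n_total=100, n_predictive=3,
            heritability=0.2, m=1600, difficulty="easy", replicates=replicates,
        )
    )
    # univariate: h2 x difficulty
    for h2 in (0.05, 0.1, 0.2, 0.4):
        for diff in ("easy", "hard"):
            configs.append(
                ExperimentConfig(
                    group="univariate", order=1, n_total=100, n_predictive=1,
                    heritability=h2, m=1600, difficulty=diff,
                    replicates=replicates, prevalence=0.5,
                )
            )
    # additive effects (non-epistatic); ratio = per-locus variance shares
    for ratio in ((50, 50), (75, 25)):
        configs.append(
            ExperimentConfig(
                group="additive2", order=1, n_total=100, n_predictive=2,
                heritability=0.4, m=1600, subgroup_ratio=ratio,
                replicates=replicates, prevalence=0.5,
            )
        )
    configs.append(
        ExperimentConfig(
            group="additive4", order=1, n_total=100, n_predictive=4,
            heritability=0.4, m=1600, replicates=replicates, prevalence=0.5,
        )
    )
    return configs


# ---------------------------------------------------------------------------
# Tab-delimited dataset IO (GAMETES-style)
# ---------------------------------------------------------------------------


def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write a dataset as tab-delimited text with a final 'Class' column."""
    dataset.validate()
    df = pd.DataFrame(dataset.genotypes, columns=dataset.feature_names)
    df["Class"] = dataset.labels
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path, replicate_seed: int = 0, config_id: str = "") -> GenotypeDataset:
    """Read a GAMETES-style tab-delimited dataset.

    Predictive columns are recognized by the ``M<i>P<j>`` naming convention.
    Malformed cells raise :class:`FormatError` naming the row and column.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[-1] != "Class":
        raise FormatError(f"{path}: last column must be 'Class', got {df.columns[-1]!r}")
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           | (pd.to_numeric(df[col], errors="coerce") % 1 != 0)]
            row = int(bad[0]) if len(bad) else 0
            raise FormatError(f"{path}: non-integer value in column {col!r}, row {row}")
    genotypes = df.iloc[:, :-1].to_numpy()
    labels = df["Class"].to_numpy()
    bad = np.argwhere(~np.isin(genotypes, (0, 1, 2)))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: genotype value {genotypes[r, c]} outside {{0,1,2}} "
            f"at row {r}, column {df.columns[c]!r}"
        )
    if not np.isin(labels, (0, 1)).all():
        row = int(np.argwhere(~np.isin(labels, (0, 1)))[0][0])
        raise FormatError(f"{path}: Class value outside {{0,1}} at row {row}")
    names = list(df.columns[:-1])
    predictive = tuple(i for i, nm in enumerate(names) if _PREDICTIVE_NAME.match(nm))
    if not predictive:
        raise FormatError(f"{path}: no predictive (M<i>P<j>) columns found")
    return GenotypeDataset(
        genotypes=genotypes,
        labels=labels,
        predictive_idx=predictive,
        feature_names=names,
        replicate_seed=replicate_seed,
        config_id=config_id,
    )
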