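"""Simulator tests: HWE sampling, XOR construction, penetrance models, IO."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rbabench as rb
from rbabench.errors import (
    FeasibilityError,
    FormatError,
    InvalidParameterError,
)

SEED = 20250924


# ---------------------------------------------------------------------------
# HWE genotype sampling
# ---------------------------------------------------------------------------


def test_hwe_frequencies_within_binomial_error():
    rng = np.random.default_rng(SEED)
    m = 100_000
    g = rb.sample_genotypes([0.2], m, rng)[:, 0]
    expected = np.array([0.64, 0.32, 0.04])
    freqs = np.bincount(g, minlength=3) / m
    se = np.sqrt(expected * (1 - expected) / m)
    assert (np.abs(freqs - expected) < 3 * se).all()


@pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
def test_invalid_maf_rejected(maf):
    rng = np.random.default_rng(0)
    with pytest.raises(InvalidParameterError):
        rb.sample_genotypes([maf], 10, rng)


# ---------------------------------------------------------------------------
# Clean XOR construction
# ---------------------------------------------------------------------------


def test_xor_grid_enumerates_20_configurations():
    configs = rb.xor_grid()
    assert len(configs) == 20
    assert len({c.config_id for c in configs}) == 20


def test_xor_parity_definition():
    table = rb.xor_penetrance_table(2).table
    assert table[1, 0] == 1.0  # one heterozygote -> case
    assert table[1, 1] == 0.0  # two heterozygotes -> control


@pytest.mark.parametrize("order", [2, 3, 4, 5])
def test_xor_table_pure_strict_by_enumeration(order):
    """Brute-force marginalization: every proper-subset marginal is 0.5."""
    model = rb.xor_penetrance_table(order)
    w = np.array([0.25, 0.5, 0.25])  # HWE at maf 0.5
    loci = range(order)
    for r in range(1, order):
        for subset in itertools.combinations(loci, r):
            for fixed in itertools.product(range(3), repeat=len(subset)):
                total = 0.0
                for g in itertools.product(range(3), repeat=order):
                    if tuple(g[i] for i in subset) != fixed:
                        continue
                    p = np.prod([w[g[i]] for i in loci if i not in subset])
                    total += p * model.table[g]
                assert total == pytest.approx(0.5, abs=1e-12)
    ok, dev = rb.verify_pure_strict(model)
    assert ok and dev == 0.0


def test_xor_table_full_penetrance_heritability_one():
    for order in (2, 3, 4, 5):
        model = rb.xor_penetrance_table(order)
        assert model.realized_heritability() == pytest.approx(1.0, abs=1e-12)
        assert model.realized_prevalence() == pytest.approx(0.5, abs=1e-12)


def test_xor_dataset_class_balance_and_determinism():
    for order, n in [(2, 20), (5, 40)]:
        m = 1600
        ds = rb.make_xor_dataset(order, n, m, np.random.default_rng(SEED))
        ds.validate()
        assert abs(ds.labels.mean() - 0.5) < 3 * np.sqrt(0.25 / m)
        # labels are a deterministic function of the predictive genotypes
        bits = (ds.genotypes[:, :order] == 1).sum(axis=1) % 2
        assert (bits == ds.labels).all()
        ds2 = rb.make_xor_dataset(order, n, m, np.random.default_rng(SEED))
        assert (ds.genotypes == ds2.genotypes).all()


def test_xor_invalid_order_rejected():
    with pytest.raises(InvalidParameterError):
        rb.make_xor_dataset(6, 20, 100, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Penetrance-model generator
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "order,h2,difficulty",
    [(1, 0.4, "n/a"), (2, 0.1, "n/a"), (2, 0.4, "easy"), (2, 0.4, "hard"), (3, 0.2, "easy")],
)
def test_penetrance_model_recovers_parameters(order, h2, difficulty):
    """Brute-force recomputation of K and h2 over all genotype cells."""
    rng = np.random.default_rng(SEED + order)
    model = rb.make_penetrance_model(order, h2, difficulty=difficulty, rng=rng)
    # independent recomputation: direct summation over the 3**k cells
    w = {}
    for j, maf in enumerate(model.mafs):
        q = 1 - maf
        w[j] = [q * q, 2 * maf * q, maf * maf]
    K = 0.0
    for g in itertools.product(range(3), repeat=order):
        p = np.prod([w[j][g[j]] for j in range(order)])
        K += p * model.table[g]
    var = 0.0
    for g in itertools.product(range(3), repeat=order):
        p = np.prod([w[j][g[j]] for j in range(order)])
        var += p * (model.table[g] - K) ** 2
    assert K == pytest.approx(model.prevalence, abs=1e-9)
    assert var / (K * (1 - K)) == pytest.approx(h2, abs=1e-6)
    if order >= 2:
        ok, dev = rb.verify_pure_strict(model)
        assert ok, f"max marginal deviation {dev}"


def test_pinned_prevalence_is_honored():
    model = rb.make_penetrance_model(
        2, 0.1, prevalence=0.5, rng=np.random.default_rng(SEED)
    )
    assert model.realized_prevalence() == pytest.approx(0.5, abs=1e-9)


def test_infeasible_heritability_raises_with_attempts():
    with pytest.raises(FeasibilityError) as exc:
        rb.make_penetrance_model(
            3, 0.35, rng=np.random.default_rng(0), max_attempts=20_000
        )
    assert exc.value.attempts == 20_000


def test_verify_pure_strict_rejects_additive_table():
    g = np.arange(3)
    table = 0.1 + 0.1 * (g[:, None] + g[None, :])
    model = rb.PenetranceModel(
        order=2, table=table, mafs=np.array([0.2, 0.2]), prevalence=0.2,
        heritability=0.1,
    )
    ok, dev = rb.verify_pure_strict(model)
    assert not ok and dev > 1e-3


def test_verify_pure_strict_accepts_constant_table():
    model = rb.PenetranceModel(
        order=2, table=np.full((3, 3), 0.3), mafs=np.array([0.2, 0.2]),
        prevalence=0.3, heritability=0.0,
    )
    ok, dev = rb.verify_pure_strict(model)
    assert ok and dev == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def test_homogeneous_prevalence_matches_model():
    rng = np.random.default_rng(SEED)
    model = rb.make_penetrance_model(2, 0.2, rng=rng)
    config = rb.ExperimentConfig(
        group="core2way", order=2, n_total=10, n_predictive=2,
        heritability=0.2, m=100_000,
    )
    ds = rb.assemble_dataset(config, [model], rng)
    k = model.realized_prevalence()
    assert abs(ds.labels.mean() - k) < 3 * np.sqrt(k * (1 - k) / config.m)


def test_heterogeneous_split_sizes_and_columns():
    rng = np.random.default_rng(SEED)
    models = [rb.make_penetrance_model(2, 0.4, rng=rng) for _ in range(2)]
    config = rb.ExperimentConfig(
        group="hetero2way", order=2, n_total=20, n_predictive=4,
        heritability=0.4, m=1600, subgroup_ratio=(75, 25),
    )
    ds = rb.assemble_dataset(config, models, rng)
    ds.validate()
    assert ds.predictive_idx == (0, 1, 2, 3)
    assert ds.feature_names[:4] == ["M0P0", "M0P1", "M1P0", "M1P1"]
    assert ds.n_instances == 1600  # 1200 + 400 governed by models A and B


def test_heterogeneous_bad_ratio_rejected():
    config = rb.ExperimentConfig(
        group="hetero2way", order=2, n_total=20, n_predictive=4,
        heritability=0.4, m=100, subgroup_ratio=(70, 20),
    )
    rng = np.random.default_rng(0)
    models = [rb.make_penetrance_model(2, 0.1, rng=rng) for _ in range(2)]
    with pytest.raises(InvalidParameterError):
        rb.assemble_dataset(config, models, rng)


def test_additive_combined_on_penetrance_scale():
    rng = np.random.default_rng(SEED)
    config = rb.ExperimentConfig(
        group="additive2", order=1, n_total=10, n_predictive=2,
        heritability=0.4, m=50_000, subgroup_ratio=(50, 50), prevalence=0.5,
    )
    ds = rb.generate_dataset(config, 0, seed_base=SEED)
    ds.validate()
    assert ds.predictive_idx == (0, 1)
    # combined prevalence stays near the per-locus baseline K = 0.5
    assert abs(ds.labels.mean() - 0.5) < 0.02


def test_full_grid_replicate_generation_is_deterministic():
    config = rb.table1_grid(replicates=1)[25]  # a core2way cell
    a = rb.generate_dataset(config, 0, seed_base=SEED)
    b = rb.generate_dataset(config, 0, seed_base=SEED)
    assert (a.genotypes == b.genotypes).all()
    assert (a.labels == b.labels).all()
    c = rb.generate_dataset(config, 1, seed_base=SEED)
    assert not (a.labels == c.labels).all() or not (a.genotypes == c.genotypes).all()


def test_table1_grid_shape():
    configs = rb.table1_grid()
    groups = {c.group for c in configs}
    assert groups == {
        "xor", "core2way", "featurescale", "hetero2way", "epi3way",
        "univariate", "additive2", "additive4",
    }
    assert len([c for c in configs if c.group == "core2way"]) == 32
    assert len([c for c in configs if c.group == "univariate"]) == 8
    assert all(c.replicates == 30 for c in configs)
    # scaled-down default caps the largest feature count at 10,000
    assert max(c.n_total for c in configs) == 10_000
    assert max(c.n_total for c in rb.table1_grid(full_scale=True)) == 100_000


# ---------------------------------------------------------------------------
# Tab-delimited IO
# ---------------------------------------------------------------------------


@settings(max_examples=20, deadline=None)
@given(
    order=st.sampled_from([2, 3]),
    n=st.integers(min_value=5, max_value=12),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_roundtrip_identity(tmp_path_factory, order, n, seed):
    """Write-then-read preserves genotypes, labels, names and truth columns."""
    path = tmp_path_factory.mktemp("io") / "ds.txt"
    ds = rb.make_xor_dataset(order, max(n, order), 30, np.random.default_rng(seed))
    rb.write_dataset(ds, path)
    back = rb.read_dataset(path)
    assert (back.genotypes == ds.genotypes).all()
    assert (back.labels == ds.labels).all()
    assert back.feature_names == ds.feature_names
    assert back.predictive_idx == ds.predictive_idx


def test_read_rejects_out_of_range_genotype(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("M0P0\tN0\tClass\n0\t3\t1\n")
    with pytest.raises(FormatError, match="row 0"):
        rb.read_dataset(path)


def test_read_rejects_missing_class_column(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("M0P0\tN0\n0\t1\n")
    with pytest.raises(FormatError, match="Class"):
        rb.read_dataset(path)


def test_read_rejects_non_integer_cell(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("M0P0\tClass\n0.5\t1\n")
    with pytest.raises(FormatError, match="non-integer"):
        rb.read_dataset(path)
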