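# Methods

This note documents the models, algorithms and numerical choices behind
`rbabench`, and what its synthetic data can and cannot say about real
genotype data.

## Genotype and phenotype simulation

All genotypes are minor-allele counts in {0,1,2}, sampled i.i.d. per locus
under Hardy–Weinberg equilibrium (HWE): P(0,1,2) = ((1−p)², 2p(1−p), p²)
at minor-allele frequency (maf) p ∈ (0, 0.5]. Loci are unlinked — no
linkage disequilibrium — and there is no missingness; both are deliberate
idealizations.

A k-locus **penetrance model** is a table f : {0,1,2}^k → [0,1] of case
probabilities. Under the HWE genotype distribution π:

- prevalence K = Σ_g π(g) f(g),
- heritability h² = Σ_g π(g) (f(g) − K)² / (K(1−K)).

A model is **pure** (no univariate effects) and **strict** (no lower-order
interactions) when marginalizing f onto every nonempty proper subset of
its loci — weighting the complementary loci by their HWE probabilities —
yields a constant. `verify_pure_strict` checks this by exact tensor
contraction with tolerance 1e−9; generated models achieve ~1e−16.

### Clean XOR family

Each of the k predictive loci is sampled at maf 0.5 and binarized as
b = 1 iff heterozygous (probability exactly 1/2); the class is the parity
of the bits. The implied penetrance table is 0/1 (full penetrance, h² = 1)
and every proper-subset marginal equals 1/2 exactly, so the family is
pure, strict and clean at every order 2–5. Remaining features are
independent maf-0.5 noise. There is no single canonical encoding for
XOR-style genotype interactions; the parity-of-heterozygotes construction
was chosen because every claimed property (pure, strict, fully penetrant,
non-linearly separable) follows from it provably, not just empirically.

### Noisy penetrance models (GAMETES-style)

Tables at a requested h² are found by constrained random search:

1. draw a raw table of N(0,1) deviations scaled by √π(g) (rare genotype
   cells get proportionally smaller deviations — nearly all feasible
   volume at higher h² lies there; unbiased candidates find nothing at
   h² = 0.4 in 5·10⁵ attempts);
2. project onto the pure/strict subspace by subtracting the
   probability-weighted mean along each locus axis (for order 1, simple
   centering);
3. rescale deviations so the table variance hits h²·K(1−K) exactly;
4. reject candidates leaving [0,1]; retry up to `max_attempts`
   (default 5·10⁵), then raise a feasibility error reporting attempts.

**Prevalence floats by default.** Each candidate draws its own
K ~ U(0.05, 0.95) and the realized value is recorded on the model.
Pinning K = 0.5 at maf 0.2 caps the achievable heritability of pure/strict
tables at ≈ 0.32 (2-way) and ≈ 0.18 (3-way) — below the study settings —
whereas a free K raises the ceilings to ≈ 0.56 and ≈ 0.31 (numerically
optimized bounds). This also reproduces the known simulator limitation
that pure/strict 3-way models at h² = 0.4 are unobtainable, which is why
the 3-way experiments run at h² = 0.2. `prevalence=` can still pin K where
feasible; the univariate and additive families use K = 0.5.

**Difficulty (easy/hard).** GAMETES's own ease-of-detection metric is not
reimplemented here. We generate a population of 50 valid models, score
each by the probability-weighted mean absolute penetrance deviation
relative to its standard deviation (at fixed variance this measures how
broadly the signal spreads over common genotype cells), and draw from the
top (easy) or bottom (hard) decile.

**Defaults**: maf 0.2 for predictive loci (common GAMETES practice); noise
loci draw maf ~ U(0.05, 0.5) per feature; labels are Bernoulli(f(g));
30 replicates per configuration.

### Assembly variants

- *Heterogeneous* (two independent 2-way models): instances split by the
  stated ratio (75:25 → 1200/400 of 1600); each subgroup's labels come
  from its own model while the other model's loci are carried as noise
  for that subgroup; rows are shuffled afterwards.
- *Additive* (2- or 4-locus, non-epistatic): per-locus order-1 deviations
  from K = 0.5 are summed on the penetrance scale and clipped to [0,1];
  the listed 50:50 / 75:25 variations are interpreted as per-locus shares
  of the total heritability. Clipping can perturb the realized K/h²
  slightly; the per-locus models themselves satisfy the invariants
  exactly.
- The 100,000-feature configuration runs at 10,000 features by default
  (config id records the scaling); pass `full_scale=True` /
  `--full-scale` to override.

Everything is reproducible bit-for-bit: every dataset seed derives from
(seed base, config id, replicate index) via BLAKE2s, and each
configuration's penetrance model derives from (seed base, config id) so
all replicates share one architecture.

## Relief-based scorers

Distance is the genotype mismatch count (Hamming; per-feature diff 0/1),
computed exactly via one-hot inner products. All m instances serve once as
target; binary outcomes only (the multi-class miss prior reduces to 1).

- **ReliefF** selects the NN nearest hits and NN nearest misses per target
  (ties broken by ascending instance index for determinism) and updates
  w_f += (Σ_miss diff − Σ_hit diff)/(m·NN). If a target has fewer than NN
  hits or misses, all available are used (one warning per dataset) and
  that side is normalized by its own count. The study's settings are
  NN = 10 and NN = 100.
- **MultiSURF** defines per target i a threshold T_i (mean distance to all
  other instances) and dead-band D_i = 0.5 σ_i; instances with
  d < T_i − D_i are near, d > T_i + D_i far. Near hits and near misses
  update scores, each side normalized by its own member count (empty sides
  contribute nothing); far instances are ignored.
- **MultiSURF\*** additionally scores far instances with inverted sign
  (far-hit differences add, far-miss differences subtract), normalized
  analogously. The per-target near and far terms are averaged (factor ½)
  so all weights stay in [−1, 1]; this is a global rescaling and cannot
  change any ranking. The dead-band multiplier (default 0.5) is exposed
  as a knob.

Internally the per-target mismatch sums are integer-exact (count minus
same-genotype count via three matrix products) before normalization, so a
constant feature scores exactly 0 and the vectorized scorers agree with
naive O(m²n) reference loops to ~1e−16 (the test suite asserts 1e−12,
i.e. exact up to floating-point summation order).

## Controls

- **Mutual information**: the exact discrete plug-in estimator (nats)
  between each 3-level genotype and the binary class, via
  `sklearn.metrics.mutual_info_score`; negatives are impossible for the
  plug-in and any substituted estimator is clipped at 0. A univariate
  filter: blind to pure interactions by construction.
- **Random shuffle**: a uniformly random feature ordering, the
  no-information floor. Its weakest-link power curve has the closed form
  P(weakest ≤ p) = C(p,q)/C(n,q) for q planted features, used as an
  analytic reference in the tests.

## Ranking and power evaluation

Standard ranking sorts raw scores descending; absolute-value ranking sorts
|score| descending. Ties break by ascending feature index everywhere; a
pessimistic mode (`weakest_link_pessimistic`) reports the worst-case rank
if every tie resolved unfavorably, for sensitivity analysis. The weakest
link is the 1-based rank of the worst-ranked predictive feature; "power at
position p" counts weakest links ≤ p, so curves are monotone and end at
100%. Ten methods are reported in a fixed order (ReliefF-10NN,
ReliefF-100NN, MultiSURF, MultiSURF\*, their _ABS variants, Shuffle,
MutualInformation); heatmaps use an orange-white→blue map over [0,100]
with the numeric matrix always written as TSV — the TSV, not the image,
is the testable surface.

## Problem sizes and test design

The package's own study runs use scaled-down sizes chosen to keep each
script in the minutes range on one CPU: 5 replicates per configuration in
the analysis drivers and the score-magnitude reproduction (50 datasets of
1600 instances), 10 replicates for the clean-2-way power check, 30 for the
4-way/shuffle comparison (where the claim is statistical equivalence and
the DKW α = 0.01 band at R = 30 is the acceptance region). Replicate
counts are knobs throughout; nothing in the code depends on the scale.

## What the synthetic data does not show

HWE, unlinked loci, no missingness, exact knowledge of predictive columns
and balanced-ish classes are all idealizations. Passing power benchmarks
here demonstrates algorithmic behavior under the declared generative
models — not performance on real GWAS panels, where LD, covariates,
population structure and far larger feature counts dominate. The clean XOR
family in particular is a toy: fully penetrant parity signal at maf 0.5 is
the most favorable possible interaction geometry, which is exactly why
failure on it is informative.

## Known limitations

- Continuous phenotypes, multi-class outcomes, missing genotypes and
  iterative wrappers (TuRF and relatives) are out of scope.
- Absolute score magnitudes of MultiSURF/MultiSURF\* depend on the
  normalization convention (per-side means, far/near averaging); rank
  orders are robust to it, and all cross-checked quantities are either
  ranks or ReliefF magnitudes.
- The difficulty metric is this package's own definition; E/H labels
  order models within our generator and need not coincide with other
  simulators' easy/hard labels.
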