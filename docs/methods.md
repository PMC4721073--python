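# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `genecol`. Notation: populations (seedlots) are
indexed by *i*, chamber environments by *j*, blocks by *k*, tray
locations by *l*; all effects are random.

## Freeze-injury index

The index of injury for a sample frozen at temperature *t* is
`It = 100 (Rt − R0) / (1 − R0)` with `Rt = Lt/Lk` and `R0 = L0/Ld`.
Controls are batch-scoped: every sample row carries a `batch_id` that
joins it to one `(L0, Ld)` control pair. Because noisy controls can
produce `Rt < R0`, the raw index can be negative; the reported index is
clamped to [0, 100] by default (the raw value is always retained),
since the quantity is defined as a percent injury. Validity requires
`0 < Lt ≤ Lk` and `0 < L0 < Ld`; anything else is rejected rather than
silently propagated.

Cold hardiness is summarized from the two freeze treatments whose
across-population mean injury is nearest 50%, where discrimination
among populations is maximal; a third, less informative treatment is
accepted in the input but excluded from the summary. The
"least-squares mean" per population and chamber comes from an additive
population + treatment fixed-effects OLS fit — the minimal model that
adjusts for missing population × treatment cells; with balanced data it
reduces to the simple mean over the two treatments. Block effects are
not included in this summary model (they are absorbed later by the
variance decomposition, which sees per-seedling data).

## Variance decomposition and V_pop

Each trait is decomposed under

    Y_ijkl = mu + P_i + E_j + (PxE)_ij + B(E)_jk + L(B)_kl + e_ijkl

with six variance components. Nested factors are coded on the
interaction of their nesting chain, so block labels need only be unique
within a chamber and location labels within a block. Terms with fewer
than two effective levels are dropped with a warning; the interaction
is only fitted when both main factors vary (otherwise it would
duplicate the surviving main effect).

**Identifiability of L(B).** With one seedling per physical position,
a per-position effect is confounded with the residual. "Location" is
therefore a tray of 6 adjacent positions within a block (15 trays per
90-seedling block in the synthetic design), shared by several
seedlings; this is what makes the location variance estimable.

**REML algorithm.** Estimation works on Henderson's mixed-model
equations in lambda-scaled form, `(W'W + diag(0, λ_i I)) s = W'y`,
`λ_i = σ²_e/σ²_i`. Three EM iterations stabilize the start, then
average-information (AI) updates run to convergence (maximum relative
component change < 1e-8, iteration cap 500, error carrying the last
iterate on failure). Per-block traces of the inverse coefficient
matrix — needed by both the EM updates and the REML gradient — are
computed after absorbing the largest random-effect block (its `Z'Z` is
diagonal), so only a small dense system is factorized; at the study's
scale (2880 observations, ≈1800 random-effect levels) a fit takes
about one second. Components driven negative are pinned at zero
(active set) and stay pinned, matching the default behavior of
standard mixed-model software. The implementation is verified in the
test suite against (a) the balanced-ANOVA closed forms, (b) a dense-V
restricted-likelihood oracle, and (c) statsmodels' MixedLM variance
components on crossed fixtures.

**Standard errors** are asymptotic Wald SEs from the inverse AI matrix
at the optimum, computed for all components including pinned ones
(flagged as such), since published tables report SEs even for zero
estimates. When components are re-expressed as percent of total, SEs
are scaled by the same factor — the total is treated as a fixed scaling
constant, an approximation.

**V_pop** is `σ²_P/(σ²_P + σ²_e)`, a downward-biased proxy for Q_ST
(the denominator uses the residual instead of twice the additive
variance, which cannot be separated without pedigree). Its SE uses the
standard propagation rules, first for the sum `σ²_P + σ²_e`
(`SE² = SE_P² + SE_e²`), then for the ratio:

    SE_Vpop = V_pop * sqrt( (SE_P/σ²_P)² + (SE_{P+e}/(σ²_P+σ²_e))² )

This is undefined at `σ²_P = 0` and rejected there.

`anova_components` provides the expected-mean-squares closed forms for
balanced one-way and crossed layouts. It exists as an independent
check on the REML path and deliberately rejects unbalanced data. Note
the two coincide only when all REML estimates are interior (no
component pinned at zero), because the moment estimator does not refit
under the nonnegativity constraint.

## Trait matrix

Population × chamber trait means are normalized per chamber-trait
column to mean 0, SD 1 over populations (sample, n−1, convention:
population means are a sample of provenances). Missing cells — a
population absent from a chamber — are imputed by the k-nearest-row
rule (default k = 5): distance between populations is Euclidean over
the columns both observe, rescaled by `sqrt(n_cols/n_shared)`, and a
missing cell is filled with the mean of that column over the k nearest
populations observing it. This transparent nearest-neighbour rule
stands in for the bespoke imputation of the original analysis, whose
details are not reproducible from the publication; it matches
scikit-learn's uniform-weight KNN imputer, which the tests use as an
oracle. Imputation never changes observed cells, and normalization is
idempotent.

The default MRT response pools the normalized chamber columns per
trait and re-standardizes, justified when population × environment
interaction is weak (in both the published tables and the generator
defaults, P×E is a small fraction of the population effect). The
per-chamber 20-column response remains available as an option.

## Multivariate regression tree

The MRT greedily partitions the population × trait matrix by rules on
external predictors, each split maximizing the drop in the
multivariate sum of squared Euclidean distances to node means. Design
choices:

- **Best-first growth**: the node whose best admissible split removes
  the most SS is expanded next. This makes "the tree with n leaves"
  well defined, so fixed-size pruning (keep the first n−1 splits in
  growth order) and regrowth to size n coincide — a tested invariant.
- **Determinism**: numeric ties break toward the smaller threshold,
  categorical ties toward the lexicographically smallest left level
  set, ties across predictors toward the first column.
- **Categorical splits**: all `2^(m−1) − 1` binary level partitions are
  enumerated exactly up to 12 distinct levels. Beyond that, levels are
  ordered by the projection of their mean response onto the first
  principal axis of the level means and only contiguous partitions are
  scored; on random 8-level fixtures this heuristic reproduces the
  exhaustive optimum in ≥95% of cases (tested).
- **Controls**: `min_leaf = 2` (ecosystem units are represented by as
  few as two seedlots), `min_improvement_fraction = 0.01` of total SS
  (splits below the floor are not made), optional `max_leaves`.
- Missing predictor values are rejected; responses are imputed
  upstream, and climate predictor tables are complete by construction.
  There are no surrogate splits.

Tree size can be fixed (the reproduction mode, since published trees
are shown at chosen sizes) or selected by v-fold cross-validation:
held-out rows are routed to leaves and their SS to the assigned leaf
means, divided by the total SS, gives the relative error; both the
minimum-error size and the 1-SE size are reported.

SS conservation (`parent SS = left + right + reduction`) holds at every
node to 1e-9, the tree R² equals the sum of per-split SS fractions, and
univariate trees are verified node-for-node against scikit-learn's
best-first CART (which shares the same greedy criterion); scikit-learn
is used only as a cross-check, never as the implementation.

## Seed-zone assembly

Populations are routed through the tree; each ecosystem variant is
assigned to the leaf holding the majority of its populations, ties
going to the larger group, and variants straddling leaves are logged
as conflicts rather than hidden. A population with a categorical level
unseen in training routes to the child with more training members
(logged). Partition agreement (climate vs ecozone vs variant trees)
uses the adjusted Rand index, implemented directly from the
contingency table and cross-checked against scikit-learn. Reports are
CSV/JSON with fixed float formats and sorted keys, so identical inputs
give byte-identical files.

## Synthetic trial generator

The generator emulates the study conditions so that recovery is
testable against known truth:

- **Design**: per species, 4 chamber environments × 8 blocks × 90
  seedlings (2880 total), 254 seedlots (spruce) or 281 (pine), each
  seedlot 2–4 times per chamber. Chamber capacity is allocated evenly
  (floor/ceil) and shuffled into blocks — a randomized incomplete-block
  allocator rather than a formal resolvable α-design construction;
  downstream models treat block as an unstructured random label, for
  which even replication is the property that matters.
- **Origins**: seedlots are drawn around five western-Canada ecoregion
  archetypes (boreal plains, montane, sub-boreal plateau, wet interior
  mountains, dry warm valleys). Invariants hold by construction:
  MWMT/MCMT are positive offsets from MAT, TD is their difference,
  degree-day variables are nonnegative monotone functions of
  temperature, MSP is a fraction of MAP. Ecosystem variants hold 2–6
  seedlots and nest in ecozones, which nest in the planted groups. A
  `separation` multiplier scales between-group climate spread; 1.0 is
  the realistic default, larger values make groups cleanly separable
  for recovery oracles.
- **Traits**: each of the five traits is the literal sum of the
  decomposition model, with magnitudes defaulting to the published
  percent tables (only ratios matter downstream). The population
  effect is piecewise-constant over planted groups plus a within-group
  slope on standardized MAT deviation plus an individual deviation,
  with variance shares 0.65/0.20/0.15 by default. With G groups the
  group-effect variance carries a `G/(G−1)` factor so the marginal
  among-population variance equals the stated σ²_P (without it the
  recoverable population variance is biased low by the finite number
  of groups). Trait units are cm (height), mm (diameter),
  day-of-season (phenology) and % (cold injury); units never affect
  the normalized analyses.
- **Freeze samples**: each seedling's latent injury follows a logistic
  curve in freeze temperature — any monotone sigmoid would do; the
  logistic is chosen for closed-form inversion — anchored so its injury
  at the reference (median) test temperature equals its cold-injury
  trait. Conductances are emitted so the injury formula returns the
  latent injury exactly at zero noise (a tested round trip); noise
  perturbs Lt log-normally.

**What the generator does not emulate**: geographic climate surfaces
and spatial autocorrelation, chamber thermo-/photoperiod programming,
non-Gaussian trait distributions, measurement censoring of phenology
scores, and genotype-specific freeze-curve shapes. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to every feature of real
trials.

## Test problem sizes and tolerances

The variance-recovery check refits the full model on 100 simulated
trials at the study's size (2880 seedlings, 254 populations,
budset-like magnitudes) and requires the mean fitted V_pop within 0.02
of the generating 0.193; single-trial estimates scatter with SD ≈ 0.055
because only five group effects are drawn per trial. Sweeps over other
V_pop truths use smaller designs with proportionally widened
Monte-Carlo tolerances. The tree-recovery check uses 20 trials with
well-separated group climates (`separation = 2`) and group-dominant
population variance (between-group share 0.85, slope 0.05) — conditions
under which the planted partition is the SS-optimal one, which is what
makes ≥90% mean recovery a meaningful correctness bar for the tree; at
the default mixed shares the planted groups are often not SS-optimal
and no partitioning method could be expected to return them.

## Known limitations

- V_pop underestimates Q_ST by construction; no heritability or
  additive variance is estimated (bulk seedlots carry no pedigree).
- Percent-scale SEs treat the total variance as a constant when
  rescaling.
- The AI-REML SEs are asymptotic; for components near zero they are
  reported but flagged, and should be read cautiously.
- The categorical-split heuristic above 12 levels is not guaranteed
  optimal (exact for a one-dimensional response).
- The published study's exact variance tables, the 22% climate-tree R²
  and the 11/9-group delineations depend on the archived trial data and
  are outside what synthetic trials can or should reproduce; the
  package validates the machinery, and ships the published component
  tables as reference inputs for the V_pop worked examples.
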