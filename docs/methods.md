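# Methods

## Scope and model

`cytocycle` analyzes cells × channels tables of nonnegative ion-count
intensities (CyTOF-style) with per-cell metadata. The analysis chain assumes:

1. intensities are right-skewed and nonnegative, so variance stabilization is
   `asinh(x / c)` with cofactor c = 5 and channel scaling divides by the
   99.9th percentile (linear-interpolation percentile definition);
2. cell-cycle phase is decidable from three landmark gates (IdU for S,
   pH3(S10) for M, CyclinB1 for G2) with precedence M > S > G2 > G0G1 —
   mitotic cells do not incorporate IdU on staining timescales, and CyclinB1
   peaks in M, so the pH3 gate must dominate the CyclinB1 gate;
3. "canonical" cell state is a conjunction of per-phase marker expectations;
   any violated expectation makes the cell noncanonical (the strictest
   discretization; the per-cell violation count is retained for graded use).

## Synthetic data generator

The generator is first-class, tested code: it produces the labeled datasets
every downstream stage is validated on.

**What it emulates.** Four-phase occupancy drawn multinomially (default: the
stimulated primary T-cell occupancy 42/51/5.1/1.8 % for G0G1/S/G2/M,
renormalized to sum to one); phase-specific marker templates encoding the
qualitative dynamics reported for cycling cells — IdU positive only in S,
pH3(S10) only in M, a CyclinB1 ramp into G2/M, CDT1 licensing restricted to
G0G1, Geminin rising S→M, SLBP high in S then degraded, Ki67/PCNA/PLK1
increasing with progression, DNA content 2N→4N; multiplicative lognormal
measurement noise; per-cell-line global multiplicative offsets; drug-arrest
perturbations (occupancy shift, phase-restricted marker effects, mitotic
slippage with >4N DNA in G0G1-labeled cells); and injectable, exactly
labeled canonical-rule violations.

**Noise model.** Raw intensities are lognormal around the phase template
location with unit mean: `x = loc · exp(zσ − σ²/2)`, `σ = √ln(1 + cv²)`.
The default coefficient of variation is 0.35 — chosen once as a realistic
per-channel CV for protein CyTOF channels; `noise_cv = 0` yields exact
template values and is the basis of all exact-recovery tests. Quantitative
per-phase marker levels are not published, so template locations encode only
the reported orderings; absolute values are package choices.

**S-phase pseudo-position.** Each S cell gets u ∈ [0,1] (uniform by default;
per-line Beta when lines are configured with different replication
progression) and DNA content 2N·(1 + u). Other markers stay at their S
template level; the spec treats S as one gate and the graded DNA channel is
what the 2N→4N interpolation requires.

**Gate placement.** `recommended_raw_gates` places binary-positive gates at
the geometric midpoint of background and positive locations (symmetric under
lognormal noise) and the CyclinB1 G2 gate at the geometric midpoint of the S
and G2 levels; gates are mapped onto the analysis scale through the recorded
asinh cofactor and percentile divisors (both monotone).

**What it does not emulate.** Doublets, beads, barcodes, spillover,
acquisition-time drift, and — importantly — the sparsity and correlation
structure of real panels: every simulated marker has a nonzero background in
every phase, so simulated cells are dense positive vectors. Passing tests
demonstrate the algorithms' correctness and calibration on data with known
structure, not performance on any particular real dataset.

## Preprocessing

Anchor batch factors are computed and applied on the raw scale
(`f(c,b) = median(anchor, reference, c) / median(anchor, b, c)`): a
multiplicative ion-count correction commutes with asinh only approximately,
so correcting before transformation keeps the factor exact. Percentile
normalization defaults to no censoring at 1 (`clip_at_one=False`) to
preserve within-channel rank order; the flag exists because censoring is a
legitimate convention. Cleanup is plain per-channel (min, max) windows on
the asinh scale — a cPARP upper bound for pre-apoptotic removal and a DNA
window standing in for debris/doublet exclusion; per-rule removed counts may
overlap when one cell breaks several rules, and the retained set is
independent of rule order.

## Canonical rules

The shipped table (`data/canonical_rules.tsv`, user-replaceable) encodes six
literature expectations: Ki67 high in S; CDT1 negative after S (G2+M); pRb
(S780) high in G2; PLK1 low in G0G1; SLBP low after S; Geminin low in G0G1.
Thresholds are quantiles of each marker over all cells (published absolute
gates are not available numerically): 0.10 for "high" expectations, and
0.90/0.60/0.50 for "low/negative" expectations, placed in the density gap
between the expressing and non-expressing subpopulations of the bimodal
marker mixture. Rules are evaluated on the normalized asinh scale. At the
default noise level these thresholds give a false-noncanonical rate well
under 1 % on pure-canonical data and > 97 % sensitivity for injected
violations; at zero noise both are exact.

## Diversity

Edges use the **dissimilarity** convention — edge iff d(i,j) ≥ τ, τ = 0.5 —
because the statistic equates higher mean connectivity with higher cell-state
diversity, which holds when edges join well-separated cells; the similarity
convention is retained as an option. Subset enumeration over the 17-feature
pool is exhaustive up to `max_subsets_per_size` (default 500; 2¹⁷ subsets ×
O(n²) distances is past desk scale), with seeded uniform subset sampling
beyond the cap; exhaustive mode is seed-independent and identical to sampled
mode whenever the cap exceeds the subset count. Distances are computed on the
normalized asinh scale, with zero-norm cells excluded and counted.

On simulated data the per-size mean density *decreases* beyond small subset
sizes: simulated cells are dense positive vectors, so shared always-positive
markers dominate the dot product and pull cosine distances below τ as
features are added. Phase-discriminating subsets (IdU/pH3/CDT1-type) drive
the nonzero densities. Real CyTOF panels are sparser, which is why this
dilution is a property of the generator, not of the statistic.

## Aberrancy

NN aberrancy uses exact neighbor search, k = 10 (unpublished in the source
analysis; configurable), Euclidean metric, core-panel features. The
canonical/aberrant threshold is the α = 0.95 quantile of the reference's own
score distribution, computed leave-self-out (scoring a reference cell
against a set containing itself zero-inflates the distribution). By
construction ≈ 5 % of held-out reference-like cells are flagged. In
displacement experiments the unit of displacement is the **channel standard
deviation on the analysis scale** (the same z-score unit the statistics use):
a +2 SD displacement in three markers whose co-elevation is canonically
impossible is flagged at ≈ 100 %, whereas displacements expressed in
within-phase noise SDs move cells largely *along* the phase manifold and sit
at the flagging boundary.

Mahalanobis distances use each group's own mean and covariance (all cells of
the phase pooled, canonical and noncanonical) with ridge λ = 1e-6 for
stability. The kNN condition score — neighbor label fraction over global
prevalence, leave-self-out — is a documented simplified stand-in for
graph-signal perturbation-likelihood scoring, not a re-implementation of it.

## Statistics

Features are z-scored with the population SD (ddof = 0; a two-point channel
{0, 2} maps to {−1, +1}). Differential testing is a fixed-effects linear
model per (marker, stratum) with treatment-coded contrasts, normal-theory
Wald p-values, and BH adjustment across all tests of one invocation;
significance requires padj ≤ 0.1 **and** |coef| ≥ 0.5. Mixed/random-effect
structure is deliberately not modeled — strata here have thousands of cells
and the pseudobulk path exists for replicate-level testing; this is a
documented simplification. Variance partitioning is sequential (type-I) SS
over a fixed term order (main effects in column order, then 2-way, 3-way,
4-way interactions); on balanced designs this is order-invariant, and
aliased zero-df terms are dropped with proportion NaN. Classification is
L2-regularized multinomial logistic regression (fixed C = 1) on balanced
per-line training samples with disjoint held-out test cells; one-vs-rest
and pairwise sensitivity/specificity/accuracy come from direct confusion
counts.

## Determinism and problem sizes

Every stochastic step takes a `numpy` Generator seed; the pipeline fans one
global seed out to per-stage seeds by fixed offsets so stages re-run in
isolation reproducibly, and result tables are written with a fixed float
format so identical configurations produce byte-identical files. The test
suite and acceptance script use 10–25 k cell populations, 16 k/8 k
reference/held-out splits, 25–50 simulation seeds for error-rate estimates,
and capped diversity enumeration (≤ 20–30 subsets per size on 500–1000
subsampled cells) — sizes chosen to estimate each rate to well within its
assertion tolerance.

## Known limitations

- Template levels are qualitative; absolute marker abundances, and therefore
  absolute diversity/aberrancy magnitudes, are not comparable to any real
  dataset.
- The canonical-rule thresholds are quantile-based and data-adaptive; with
  very large injected-violation fractions (≳ 40 % of a marker's cells) the
  quantile chases the injected mass and sensitivity degrades.
- The FCS layer covers float list-mode single-dataset files only.
- G0-like sub-gating (Ki67-low ∧ pRb-low within G0G1) is available but
  disabled by default; no finer sub-phasing (early/late G1 or G2) is
  attempted.
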