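# cytocycle

Single-cell mass-cytometry (CyTOF) cell-cycle analysis: preprocessing, phase
gating, canonical/noncanonical cell-state discretization, graph-connectivity
diversity, nearest-neighbor aberrancy scoring, and the associated
differential and variance statistics — plus a ground-truth synthetic data
generator so the whole chain is testable end to end.

## The problem

Cell-cycle (CC) state is usually read out of cytometry data by manual gating
into four coarse phases (G0/G1, S, G2, M) from a handful of landmark markers
— IdU incorporation for active DNA replication, phospho-histone H3 (Ser10)
for mitosis, CyclinB1 for G2/M. That throws away most of what a 40+-marker
CyTOF panel measures: cells can carry marker combinations that violate the
canonical expectations for their phase (Ki67-low cells that are actively
replicating, CDT1 re-expressed after S-phase, SLBP not degraded at the S/G2
transition), and drug-induced arrest both shifts phase occupancy and
exacerbates these noncanonical states. This package implements that analysis
programmatically for anyone working with cytometry cell tables or FCS files.

## What it computes

- **Preprocessing** — `asinh(x / 5)` transform, per-channel normalization to
  the 99.9th percentile, anchor-sample multiplicative batch adjustment, and
  threshold cleanup (cPARP⁺ pre-apoptotic removal, DNA windows).
- **Phase gating** — threshold gates with precedence M > S > G2 > G0G1:
  pH3(S10) ≥ t_M → M, else IdU ≥ t_S → S, else CyclinB1 ≥ t_G2 → G2, else
  G0G1; thresholds manual, quantile-based, or KDE-valley.
- **Canonical rules** — a declarative TSV table of literature expectations
  (marker × phase → high/low/positive/negative). A cell violating ≥ 1 rule
  is noncanonical; per-group noncanonical fractions follow.
- **Diversity** — for a feature subset F, cells are joined by an edge when
  their cosine distance d(i,j) = 1 − xᵢ·xⱼ/(‖xᵢ‖‖xⱼ‖) on F crosses τ = 0.5;
  edge density = edges / C(n,2) summarizes cell-state diversity, swept over
  all subsets of a 17-marker pool and averaged per subset size.
- **Aberrancy** — score(cell) = mean Euclidean distance to its k = 10
  nearest untreated reference cells; cells beyond the 95th percentile of the
  reference's own (leave-self-out) score distribution are flagged aberrant.
  Mahalanobis distance √((x−μ)ᵀΣ⁻¹(x−μ)) per phase, and a prevalence-
  normalized kNN condition score, complement it.
- **Statistics** — per-marker fixed-effects linear models with Wald tests
  and Benjamini–Hochberg FDR (significant: padj ≤ 0.1 and |coef| ≥ 0.5 on
  z-scored features); one-way ANOVA % variance explained; sequential-SS
  variance partitioning with up to 4-way interactions; pseudobulk medians;
  multinomial logistic cell-line classification on nested minimal ⊂ core ⊂
  complete marker panels.

## Worked example

```python
import pandas as pd
import cytocycle as cc
from cytocycle.preprocess import asinh_transform, percentile_normalize
from cytocycle.gating import assign_phases, thresholds_from_raw
from cytocycle.rules import evaluate_rules, load_rules, noncanonical_fraction
from cytocycle.synthetic import recommended_raw_gates

# 20,000 cells at stimulated-T-cell phase occupancy, with a 20 % Ki67-low
# violation injected into S-phase
cfg = cc.GeneratorConfig(n_cells=20_000, seed=1,
                         noncanonical_spec=[("ki67_low_in_s", "S", 0.2)])
ds = cc.simulate_population(cfg)

m = percentile_normalize(asinh_transform(ds.expression))
phases = assign_phases(m, thresholds_from_raw(m, recommended_raw_gates(cfg)))
calls = evaluate_rules(m, phases, load_rules())
print(noncanonical_fraction(calls, pd.DataFrame({"phase": phases})))
```

Output:

```
phase fractions (%):        noncanonical fraction by phase:
G0G1    42.3                phase  fraction     n
S       50.7                 G0G1     0.004  8468
G2       5.2                   G2     0.000  1050
M        1.7                    M     0.000   340
                                S     0.196 10142

gating agreement with ground truth: 99.8%
```

The gated phase fractions recover the configured occupancy (42 % G0G1, 51 %
S, 5.1 % G2, 1.8 % M); the injected 20 % S-phase violation is recovered as a
0.196 noncanonical fraction in S, with a background false-call rate below
half a percent elsewhere.

A full pipeline run (simulate → preprocess → gate → rules → diversity →
aberrancy → differential) is one call — `cytocycle run config.yaml` from the
shell, or `cytocycle.run_pipeline(PipelineConfig(...))` from Python — and
writes `cell_table.csv`, `noncanonical_fractions.csv`,
`diversity_curve.csv`, `differential.csv`, and `run_report.json` into the
output directory, byte-identically for a fixed seed.

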