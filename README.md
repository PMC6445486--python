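# mirtraj

Integrative transcriptomic analysis for 2-genotype × 2-stage RNA-seq designs:
trajectory-class differential expression and anti-correlation-based
nomination of miRNA regulators.

The package targets studies of the kind where wild-type (WT) and knockout
(dKO) embryonic stem cells are profiled before (ESC) and after retinoic-acid
differentiation (RA), by both mRNA-seq and small-RNA-seq, and the question is
which genes and miRNAs respond to differentiation, how the mutation modifies
that response, and which miRNAs plausibly drive the mRNA changes. Because no
public count data accompany such designs in general, the package ships a
seeded synthetic-data generator with a planted ground-truth ledger, so the
whole pipeline is exercised — and scored — end to end.

## What it computes

Starting from feature × sample integer count matrices and a sample design
table, the pipeline runs:

1. **TMM normalization** — per-sample scaling factors from the trimmed
   (30% on M-values, 5% on A-values), inverse-asymptotic-variance-weighted
   mean of per-gene log-ratios against a reference sample; log₂ CPM with a
   depth-scaled prior; per-feature z-scores.
2. **NB exact test at fixed dispersion** — counts scaled to a common
   effective library size; conditional on a feature's total *t*, the group-A
   sum follows a beta-binomial BB(*t*, n_A/φ, n_B/φ) under the null
   (variance = μ + φμ², φ = 0.1 by default); the two-sided p doubles the
   smaller tail. DE calls use raw p < 0.05, |log₂FC| > 0.75, log₂CPM > 0.
3. **Trajectory classes** — genes/miRNAs significant in *both* the
   differentiation contrast (WT-RA vs WT-ESC) and the genotype contrast
   (dKO-RA vs WT-RA) are assigned to up_up, up_down, down_up or down_down
   (differentiation direction first, genotype-effect direction second).
4. **Gene-set enrichment** — one-sided Fisher exact (hypergeometric upper
   tail) of each class against GMT collections, BH FDR across the table.
5. **miRNA regulator nomination** — Pearson correlation of each annotated
   miRNA→target pair across all samples (standardized expression); per-miRNA
   one-sample, one-sided Wilcoxon signed-rank test for a negative shift of
   its target correlations; candidates are miRNAs in a down class (opposite
   to their up-class targets) with shift p < 0.05, ranked by p.
6. **Recovery scoring** — on synthetic data, regulator recall/precision and
   per-class sensitivity/specificity against the planted truth.

## Worked example

```python
from mirtraj import SimulationConfig, run_pipeline, simulate_dataset

artifacts = run_pipeline({"n_genes": 2000, "n_mirnas": 100,
                          "n_regulator_mirnas": 10, "targets_per_mirna": 15,
                          "seed": 7}, "out/")
print(open("out/run_log.txt").read())
```

prints the per-stage tallies, e.g.

```
[differential_expression] mrna/diff: tested=2000 up=333 down=331
[differential_expression] mrna/geno: tested=2000 up=224 down=208
[trajectory_classes] mrna classes: up_up=91 up_down=99 down_up=100 down_down=87
[regulators] edges tested=1500 mirnas tested=100 candidates=11
[recovery] regulator recall=1.000 precision=0.9090909090909091
```

meaning 664 genes responded to RA differentiation, 432 to the genotype at the
RA stage, 377 fell in the four joint classes, and 11 candidate miRNAs were
nominated — all 10 planted regulators recovered, with one false nomination.
`out/regulators.tsv` lists each candidate's class flavor
(down_enhanced / down_counteracted), mean target correlation, Wilcoxon shift
p, rank, and its anti-correlated up-class targets.

The scripts in `examples/` walk through each capability one at a time
(simulation, DE, classes, enrichment, regulators, full pipeline); each prints
the numbers it computes and a line on how to read them. A thin CLI mirrors
the stages: `mirtraj simulate|normalize|de|classify|enrich|regulators|run`.

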