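# mexnet

Detection of **mutually exclusive somatic-mutation modules** in cancer
cohorts, their projection onto canonical pathway graphs, and survival
analysis of the resulting subnetworks.

## The problem

Driver mutations in a cancer pathway tend to be mutually exclusive: one hit
per pathway per tumor is usually enough, so two genes operating in the same
pathway rarely carry mutations in the same sample. Recurrence-based driver
detection misses genes mutated in < 5% of samples; exclusivity *patterns*
across many gene pairs can still reveal them. mexnet is aimed at
computational cancer biologists who have somatic mutation calls (MAF or a
binarized gene × sample matrix), a pathway topology, and a clinical table,
and want to go from raw calls to survival-annotated pathway subnetworks in
one reproducible pipeline.

## The method

1. **Pairwise association.** For every pair of genes mutated in ≥ 3
   samples, the 2×2 table of joint mutation status is tested with a
   two-sided Fisher exact test (probability method, exact integer tie
   handling) and a logistic regression of one gene's status on the other.
   A pair is *mutually exclusive* when OR < 1, the logistic slope β < 0,
   and the Fisher p < 10⁻³. Zero cells use the Haldane–Anscombe 0.5
   correction; under complete separation |β| is capped at 20.
2. **Graph clustering.** Flagged pairs with p below a stringent edge
   cutoff (default 10⁻⁸, tunable over a grid toward 5–10 modules) form a
   graph with edge weight −log₁₀ p, partitioned by the Louvain algorithm
   (seeded restarts + deterministic refinement, maximizing weighted Newman
   modularity Q). Modules under 3 genes are dropped.
3. **Pathway overlay.** Each module is intersected with a pathway graph;
   connected components with ≥ 3 genes become subnetworks, scored by
   Fisher's method on their pair p-values: X = −2Σln pᵢ ~ χ²(2k).
4. **Survival.** Samples are grouped *mutated / non-mutated* by each
   subnetwork's gene set (and each member gene); groups are compared by
   log-rank test and a Cox proportional-hazards model adjusted for age and
   sex, with Benjamini–Hochberg FDR across the batch.

A synthetic-cohort generator (`mexnet simulate`) plants exclusive modules,
a matched toy pathway and survival effects, so the full pipeline is
testable offline.

## Worked example

Simulate a 400-sample cohort with three planted exclusive modules (sizes
5, 5, 4; coverage 0.9; 1% passenger noise) and a hazard ratio of 2.0 for
samples mutated in the first module, then run the pipeline:

```sh
cat > spec.yaml << 'YAML'
n_samples: 400
n_background_genes: 20
background_rate: 0.01
modules: [[5, 0.9], [5, 0.9], [4, 0.9]]
survival: [2.0, 0.002, 0.001]
YAML
mexnet simulate --spec spec.yaml --seed 7 --out-dir cohort

cat > run.yaml << 'YAML'
matrix: cohort/matrix.tsv
pathway: cohort/pathway.tsv
clinical: cohort/clinical.tsv
out_dir: results
edge_cutoff: 1.0e-4
seed: 7
YAML
mexnet run --config run.yaml
```

which prints

```
associate: 34 genes tested, 351 pairs, 26 mutually exclusive
cluster: cutoff 0.0001, 23 edges kept, 3 modules of size >= 3
map: 3 subnetworks kept
survive: 17 bases tested
wrote 4 result tables to results
```

`results/subnetworks.tsv` holds the three recovered subnetworks with
their combined p-values (e.g. `M01G02-M01G03`, 5 genes, 10 exclusive
pairs, combined p ≈ 9.4 × 10⁻⁴⁴), and `results/survival.tsv` shows the
point of the exercise — the subnetwork-level group is significant while
no individual member gene is:

```
basis           n_mutated  hr     coxph_p      fdr
M01G02-M01G03   363        2.21   4.06e-04     6.90e-03
M01G01          74         0.93   6.06e-01     8.82e-01
M01G02          53         1.09   5.98e-01     8.82e-01
...
```

Grouping by the whole subnetwork pools its low-frequency carriers
(n = 363 vs ≤ 81 per gene), recovering the planted hazard ratio of 2
(ĤR = 2.21, FDR < 0.05) that every single-gene test misses.

Per-stage subcommands (`associate`, `cluster`, `map`, `survive`,
`simulate`) consume and produce the same TSV artifacts as the full run;
every output carries a header with version, seed and thresholds, and
reruns are byte-identical.

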