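# eealineage

Tools for asking an evolutionary question of bulk tumor transcriptomes: which
gene-expression changes are so recurrent across patients that they must have
arisen early in tumor development — and are not explained by DNA copy-number
amplification or mutation?

`eealineage` implements the full analysis as a tested pipeline:

1. **Stage-wise differential expression.** For each tumor stage versus the
   normal pool, the cohort fold change is
   `FC_g = log2( ave(E_g^tumor) / ave(E_g^normal) )`, tested with an
   empirical-Bayes moderated t-statistic (gene-wise variances shrunk toward a
   moment-estimated prior, Smyth-style) and Benjamini–Hochberg FDR. Default
   gates: `|log2FC| ≥ 1` (twofold) and `FDR ≤ 0.01`.
2. **Per-patient recurrence.** Each tumor is compared individually to the
   normal mean, `FC_{g,j} = log2( E_{g,j} / ave(E_g^normal) )`; genes above
   threshold in ≥ 70 % of patients are the *frequent* upregulated set.
3. **Copy-number concordance filter.** Genes amplified in ≥ 40 % of
   patients are recurrently amplified; cytobands where ≥ 40 % of genes are
   recurrently amplified are amplified regions. A gene is CNA-driven when its
   amplified/non-amplified expression difference is ≥ 1 log2 unit at
   FDR < 0.01 (moderated t), or when Pearson r between log2 expression and
   the integer call exceeds 0.3. Removing region-resident, CNA-driven,
   mutated and ambiguous-locus genes leaves the **exclusively
   expression-altered (EEA)** genes.
4. **Lineage reconstruction.** Patients are clustered on their binary EEA
   upregulation profiles (Euclidean distance, Ward linkage, k = 4); cluster
   mean profiles plus an all-zero "normal" taxon feed Saitou–Nei
   neighbor-joining. The cluster with the shortest tree path to normal is the
   earliest subpopulation.
5. **Early-burst call.** Each gene's per-cluster upregulation fraction `p_g`
   is assigned to the nonzero binary subset vector `v` maximizing
   `cos(p_g, v) = p_g·v / (‖p_g‖‖v‖)`; genes whose subset covers the
   earliest cluster are the early-burst set.
6. **Outcome.** A multivariate Cox model over the early-burst panel yields a
   per-patient score `Σ_g β_g x_g`; a median split is compared with
   Kaplan–Meier curves and the log-rank test. EEA-vs-tumor-suppressor
   Pearson correlation matrices are also provided.

A seeded synthetic-cohort generator (`eealineage.synthetic`) plants
early-burst, late-subset, downregulated and amplification-driven genes with
known truth labels, so every stage is verifiable without external data.

## Worked example

```python
from eealineage import CohortConfig, generate_cohort, run_pipeline

cohort = generate_cohort(CohortConfig(seed=7))     # 2000 genes, 150 tumors, 50 normals
result = run_pipeline(cohort.expression, cohort.samples,
                      cohort.genes, cohort.cna)
print(result.manifest.counts)
print(result.earliest, result.lineage.newick())
```

prints (seed 7):

```
de_up_any_stage = 205        # genes called up in at least one stage
frequent_up = 125            # of those, above threshold in >= 70% of patients
removed_region = 40          # inside called amplified regions
removed_association = 40     # CNA-associated expression difference
removed_correlation = 40     # expression tracks the copy-number call
eea = 85                     # exclusively expression-altered genes
early_burst_inclusive = 83   # assigned to subsets covering the earliest cluster
earliest: C1
((C2:0.599,C3:0.535)n2:0.056,(C4:0.585,(C1:0.599,normal:7.169)n1:0.291)n3:0.0)root;
logrank p: 8.74e-07
```

The 40 planted amplification-driven genes are removed three times over
(region, association and correlation screens all catch them), the 83 planted
early-burst genes are recovered exactly, and the long branch from `normal`
to the cluster taxa against the short inter-cluster branches is the
punctuated-burst signature: most upregulation events are already present in
the earliest cluster. The multivariate-score median split separates survival
at log-rank p ≈ 9e-7 because the generator links hazard to early-burst
expression.

A shell interface mirrors the stages:

```bash
eealineage simulate --outdir cohort/ --seed 7
eealineage run-all --expression cohort/expression.tsv --samples cohort/samples.tsv \
    --genes cohort/genes.tsv --cna cohort/cna.tsv --outdir out/
```

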