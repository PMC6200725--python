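# Methods

## Scope and model

`eealineage` treats bulk tumor transcriptomes as a record of tumor
evolution. The working hypothesis is that expression changes shared by
nearly all patients arose earlier in tumor development than changes found in
patient subsets. The pipeline therefore (i) finds genes recurrently
upregulated across patients, (ii) removes genes whose upregulation is
plausibly a by-product of DNA amplification or mutation, (iii) reconstructs
a lineage over patient clusters from the surviving binary upregulation
profiles, and (iv) asks whether the genes attributed to the earliest cluster
carry prognostic signal.

Expression is assumed non-negative and roughly log-normal: all significance
testing operates on `log2(x + c)` with pseudocount `c = 1` (configurable),
while the two fold-change statistics follow their definitions exactly —
linear-scale group means inside a log2 ratio.

## Differential expression

The moderated t-test is a two-sample empirical-Bayes test. Gene-wise pooled
variances `s_g^2` on `df = n1 + n2 − 2` degrees of freedom are modeled as
`s_g^2 ~ s0^2 · F(df, d0)`; `(d0, s0^2)` are recovered by matching the mean
and variance of `log s_g^2` through digamma/trigamma identities, with the
trigamma inverse solved by Newton iteration. The posterior variance
`(d0·s0^2 + df·s_g^2) / (d0 + df)` replaces `s_g^2` in the t statistic,
referred to a t distribution on `df + d0` degrees of freedom. When the
observed spread of log variances is no larger than sampling noise, `d0 = ∞`
and all genes share `s0^2`. Setting `d0 = 0` recovers the ordinary pooled
t-test exactly; the suite verifies both this limit and, independently,
agreement with limma's `eBayes` to ~1e-10 on a fixed matrix.

Benjamini–Hochberg adjustment wraps `statsmodels.multipletests`; NaN
p-values (untestable genes) propagate rather than enter the ranking.
Boundary semantics are inclusive everywhere (`FDR ≤ 0.01`, `|log2FC| ≥ 1`,
frequency `≥ 0.70`, amplification recurrence `≥ 0.40`) except the Pearson
cutoff, which is strict (`r > 0.3`) as conventionally written; each
inclusive rule has a strict-mode switch.

### Threshold defaults

| parameter | default | meaning |
|---|---|---|
| `fdr_threshold` | 0.01 | BH gate for DE and the CNA association test |
| `log2fc_threshold` | 1.0 | twofold on the linear scale; a fourfold profile (2.0) ships for sensitivity analysis |
| `min_frequency` | 0.70 | fraction of patients for the frequent-gene filter |
| `amp_call_threshold` | 1 | CNA call counting as amplified (2 = high-level only) |
| `min_amp_fraction` / `min_region_fraction` | 0.40 | recurrent amplification and region calls |
| `corr_cutoff` | 0.3 | Pearson r flagging CNA-driven expression |
| `k_clusters` | 4 | patient clusters; a silhouette score is reported to justify k |
| `min_stage_samples` | 5 | stages with fewer tumors are dropped from stage-wise DE |

The twofold default resolves an ambiguity between a stated twofold minimum
requirement and per-patient thresholds of ±2 on a log2 quantity (fourfold);
the explicit statement of intent wins, and the threshold is a single
configurable shared by the cohort and per-patient statistics.

## CNA concordance

The association screen compares log2 group means of amplified (S1) versus
non-amplified (S2) patients per gene, with the same variance-shrinkage
machinery applied across tested genes and BH across genes; a flag requires a
positive difference ≥ 1 log2 unit and FDR < 0.01. Genes with fewer than two
patients in either group are *indeterminate*: they cannot be tested, and are
excluded from the EEA set only when amplified in ≥ 90 % of patients (such a
gene cannot be cleared of copy-number drive). Region calling uses the genes
present in the CNA matrix as each cytoband's denominator. When a gene
carries several removal reasons, the recorded primary reason follows the
fixed precedence region > association > correlation > mutated > ambiguous;
the EEA set itself is the frequent set minus the union, so precedence
affects reporting only.

## Lineage and subset assignment

Clustering is agglomerative (default Ward; the linkage was not prescribed,
and Ward on Euclidean distances over binary rows is stable and standard) cut
at `k = 4`. Neighbor-joining is the textbook Saitou–Nei algorithm — Q-matrix
joins with the standard branch-length formulas — implemented in-package and
cross-checked in tests against scikit-bio's NJ and against exact additivity
on random additive matrices. Negative branch lengths are clamped to zero
with the raw value logged. The tree is built over the k cluster mean
profiles plus an all-zero taxon named `normal`, representing the
expression state before any upregulation event; the earliest cluster is the
leaf with minimal path length to `normal`, ties broken toward the smallest
label with a warning.

Subset assignment enumerates the `2^k − 1` nonzero binary vectors in
ascending binary order — for k = 4, `(0,0,0,1)` through `(1,1,1,1)` — and
assigns each gene the vector with maximal cosine similarity to its
per-cluster upregulation fraction vector. Cosine ties prefer fewer ones,
then ascending binary order (parsimony: attribute an event to as few
subpopulations as the data demand). All-zero profiles are unassigned. The
early-burst call is reported in two tiers: *inclusive* (assigned subset has
a 1 at the earliest cluster's position, which includes the all-ones vector)
and *strict* (exactly the singleton subset of the earliest cluster), since
either reading is defensible; the inclusive tier is the pipeline's primary
output.

## Outcome

Cox fits use lifelines (Efron ties). Expression enters as per-gene
standardized `log2(x + 1)`. A joint fit is refused when the panel exceeds
half the patient count — the partial likelihood is ill-conditioned there —
and falls back to per-gene univariate coefficients with a warning;
non-convergence triggers one ridge-stabilized retry (penalizer 0.1),
recorded in the result. The pipeline selects the score panel as early-burst
genes with univariate Cox p ≤ 0.05 (the selection rule was an open design
point; univariate pre-selection in the analyzed cohort is the simplest
defensible default and is configurable). The multivariate score is the
coefficient-weighted sum of the same standardized matrix the coefficients
were estimated on; the generic `multivariate_score` combines raw values
unless asked to standardize. Median-split ties go to the low group, which
keeps the split deterministic and near-balanced.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes, with
ground truth for every planted signal. Defaults are the package's documented
study conditions: 2,000 genes; tumors 50/50/50 across stages I–III; 50
normals; 83 early-burst genes; 120 late genes; 100 downregulated genes; 40
CNA-driven genes; log2 effect 2.0; penetrance 0.9; per-gene log2 noise SD
0.5; 4 planted clusters. Baseline log2 abundance is uniform on (4, 9) —
a typical microarray-like dynamic range. Where counts were not prescribed
(late/down genes, noise), values were chosen once as realistic for a
moderately powered cohort and are not calibrated against any test outcome.

Mechanics worth knowing:

* **Early-burst genes** gain the effect in a Bernoulli(penetrance) draw of
  all tumors, independent of cluster — they are the shared block.
* **Late genes** gain the effect only in tumors of a cluster subset drawn
  from the nonzero subsets *excluding cluster 1*, so the planted lineage has
  a well-defined earliest subpopulation. At default penetrance these genes
  sit below the 70 % frequency filter, so the pipeline's EEA set is
  essentially the early-burst block; cluster-recovery of the late-gene
  structure is exercised at module level on the binary profiles directly.
* **CNA-driven genes** have call +2 exactly in their carrier tumors (carrier
  fraction = penetrance, so they pass the frequency filter and genuinely
  stress the concordance screens) and are grouped into dedicated cytobands
  of 25 genes so the region screen fires; background calls elsewhere are ±1
  noise at rate 0.05.
* **Survival** is exponential with baseline hazard 0.1 and a log-linear
  effect (coefficient 0.7) of the mean standardized log2 expression of the
  first five early-burst genes; censoring is an independent uniform horizon
  solved numerically to hit the target censoring fraction (0.3) under the
  baseline hazard.

What the generator does **not** emulate: negative-binomial count noise,
batch effects, stage-dependent effect sizes, subclonal or segment-level
copy-number structure, and correlated gene-gene noise. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real sequencing data.

## Numerical and degenerate-input choices

* Pseudocount 1 before every log2 transform; the raw fold-change functions
  default to pseudocount 0 and raise, naming the gene, on a zero normal mean.
* Zero residual variance: the shrunken posterior variance is used; if the
  prior is also degenerate the gene is flagged untestable (NaN t and p).
* Zero-variance vectors in any Pearson computation yield NaN, never a flag.
* Identical taxa are joined at zero branch length with a warning.
* All randomness in the generator flows through one `numpy` Generator seeded
  from the config; the pipeline itself draws no random numbers, so a run is
  a pure function of (inputs, config).

## Problem sizes in the verification suite

The acceptance checks run 20 full-pipeline cohorts at the default study
conditions (~3 s each), 20 null cohorts through stage-wise DE, 100
median-split log-rank simulations at n = 200, 50 random additive matrices of
4–8 taxa, 2,160 BH permutation checks and 1,000 brute-force cosine
assignments — about 90 s end to end on one CPU.

## Known limitations

* The moderated-t prior is the plain moment estimator; no robustification
  against variance outliers and no intensity-dependent trend.
* The association screen's per-gene group splits make gene-wise residual
  degrees of freedom unequal; the prior is fitted at the median df.
* Neighbor-joining on k + 1 taxa is exact for additive distances, but
  cluster-mean profiles are not guaranteed additive; branch lengths are
  interpretable only comparatively.
* The Cox stage assumes proportional hazards and reports convergence
  diagnostics only; no formal PH tests.
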