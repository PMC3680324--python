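# clustermir

Coordinated-deregulation analysis of genomic miRNA clusters, built around the
question of whether an entire cluster — such as the imprinted miR-379/miR-656
cluster on human 14q32.31 (the "C14" cluster, 52 mature miRNAs inside the
DLK1-DIO3 locus) — behaves as one transcriptional unit that is switched off in
cancer. The package is aimed at computational biologists who have per-sample
normalized expression, methylation and qPCR tables (TCGA level-3-style
extracts or their own) and want the whole chain of evidence as a tested,
scriptable pipeline rather than a pile of one-off scripts.

## What it computes

**Per-feature differential expression.** For each miRNA (or mRNA) the
two-tailed Mann-Whitney U test compares cases against controls; direction
comes from the matching one-tailed tests. p-values are Bonferroni-corrected
(p·N over the N features actually tested, capped at 1; Benjamini-Hochberg FDR
is available), and a feature is called *down* when its corrected one-tailed
case &lt; control p falls below α.

**Cluster enrichment.** Down calls are tabulated into a 2×2 — cluster vs
non-cluster complement, down vs not-down — and tested with the Pearson
chi-square test of proportions (1 df, optional Yates correction). A
descriptive random-set null (default ten draws of non-cluster feature sets of
the cluster's tested size, without replacement) reports the range, mean and
Student-t 95% CI of the null down counts, plus an empirical tail probability.

**Regional methylation.** Illumina 450K-style M-values convert to
beta-values via β = 2^M / (2^M + 1). A region's score is the median of all
its pooled probe-by-sample betas; median β &gt; 0.8 is called hypermethylated,
&lt; 0.2 hypomethylated. The target region is tested against probe-count-matched
random regions (±10% probes, disjoint) with a one-tailed Welch t-test, both on
pooled betas and on per-region medians.

**Consensus targets and pathway enrichment.** A predicted miRNA binding site
enters the consensus only when two independent predictors report it at
identical genomic coordinates; a (miRNA, 3'UTR) pair predicted by both but
never at the same position is excluded outright. Consensus genes are scored
against GMT gene sets with the EASE statistic — the hypergeometric upper tail
with one gene removed from the overlap, P(X ≥ k−1) — with a minimum-overlap
filter and multiplicity correction.

**qPCR ΔΔCt classification.** Duplicate wells are averaged; ΔCt normalizes
each assay to the mean reference-assay Ct within the sample (e.g. miR-92a or
B2M); ΔΔCt subtracts the mean control ΔCt; fold change is 2^(−ΔΔCt). Fold
change ≤ 0.6 is *down* (at least 40% loss), ≥ 2 *up*, boundaries inclusive.

A first-class synthetic-data generator (`clustermir.simulate`) emulates every
input — expression matrices with a planted deregulated cluster, methylomes
with a flagged hypermethylated region, predictor site lists with known
consensus structure, and Ct tables with planted fold changes — each paired
with a truth table, so the whole pipeline is testable without any downloads.

## Worked example

```python
import clustermir as cm

spec = cm.SimulationSpec(seed=1)          # 534 miRNAs, 38-member cluster,
matrix, truth = cm.simulate_expression(spec)  # 20+20 samples, -2 log shift
cfg = cm.RunConfig(rng_seed=1)

de = cm.call_features(matrix, cfg)
print(de.summary())

cluster = cm.ClusterDefinition.from_ids(
    "C14", truth[truth.is_cluster].feature_id)
print(cm.assess_cluster(de, cluster, cfg).summary())
```

prints

```
Differential expression: 534 features tested, 112 down, 75 up, 347 unchanged; 0 skipped for missing data.
Cluster C14: 38/38 members down (100.0%) vs background 74/496 (14.9%).
Cluster accounts for 33.9% of all down-regulated features.
Chi-square test of proportions: chi2 = 154.15, p = 2.15e-35.
Random-set null (10 sets of 38): down counts ranged 2-10, mean 6.00; 95% CI of the mean 4.22-7.78.
```

All 38 planted cluster members are recovered as down-calls, while random
38-feature sets contain only ~6 down calls each — the chi-square on the 2×2
says that contrast is nowhere near chance. The same stages are exposed on the
command line (`clustermir simulate | de | cluster-test | methyl | targets |
enrich | qpcr | all`), writing per-stage TSV tables and a deterministic
`summary.json`:

```bash
clustermir simulate --seed 3 --out-dir sim
clustermir cluster-test --expression sim/expression.tsv \
    --labels sim/labels.tsv --cluster sim/cluster.txt --out-dir out
```

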