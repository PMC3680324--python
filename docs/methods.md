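# Methods

This note documents the statistical procedures implemented in `clustermir`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical corner cases.

## Differential expression (`clustermir.de`)

Inputs are feature-by-sample matrices of *already normalized* log expression
(level-3-style data); the pipeline treats values as generic log-scale and
never exponentiates, so the log base is irrelevant. Per feature, the
two-tailed Mann-Whitney U test decides significance and the two one-tailed
tests decide direction. The exact enumeration null is used when both groups
have ≤ 8 observations and the pooled sample is tie-free; otherwise the normal
approximation with tie-corrected variance and continuity correction. A pooled
sample with all values identical returns p = 1 (no ordering information).
When the matrix is complete and both groups exceed the exact-test range, all
features are tested in one vectorised asymptotic pass per tail, which keeps
hundreds of Monte-Carlo cohorts affordable on one CPU.

Multiplicity correction is Bonferroni by default — p·N capped at 1, with N
the number of features *actually tested* (features missing a group are
skipped and reported, not counted) — or Benjamini-Hochberg step-up. A
`none` setting exists because calibration runs on global-null data need raw
calls: corrected calls are (by design) almost never made there, which would
leave the cluster 2×2 with an empty margin. Directional calls use the
one-tailed p corrected by the same N; whether a two-tailed pass should also
be required is genuinely open, so it is a config switch
(`require_two_tailed`, default off). The median case−control difference is
reported for annotation and plotting only; it never gates a call.

## Cluster enrichment (`clustermir.cluster`)

The 2×2 table is cluster vs the *non-cluster complement* (down / not-down).
Using the complement rather than the whole feature universe keeps cluster
members off both sides of the comparison; the "cluster share of down calls"
statistic (cluster down / all down) is reported separately for bookkeeping
against the genome-wide total. The test is Pearson's chi-square with 1 df;
Yates continuity correction is off by default but available — on the
published glioblastoma counts the conclusion is identical either way. A zero
margin (no down calls anywhere, or an empty group) raises rather than
returning a number, since expected counts are undefined.

The random-set null draws `n_random_sets` (default 10) sets of non-cluster
features, each the size of the cluster's tested intersection, without
replacement within a set. It is reported descriptively — min, max, mean and
a Student-t 95% CI of the mean (the CI method is a package choice; nothing
canonical exists for so few sets) — plus an empirical tail probability
(fraction of sets with at least the cluster's down count), which becomes a
usable permutation p when `n_random_sets` is raised. Significance is decided
by the chi-square; ten sets are kept as the default because with a ~500
feature pool more sets mostly resample the same features.

## Regional methylation (`clustermir.methylation`)

M-values convert to betas with β = 2^M/(2^M+1), computed as a base-2
logistic for numerical stability; the inverse (logit2) round-trips to 1e-12.
A region's score pools *all* in-region probe-by-sample betas and takes the
median; calls are strict: median > 0.8 → hyper, < 0.2 → hypo, else normal,
so a median of exactly 0.8 stays normal. Pooling inflates n for the
significance test, so two variants are reported: a one-tailed Welch t-test
of target betas vs pooled control betas (primary, matching how the region
distributions are usually plotted together), and a conservative variant
comparing the target's median against the spread of per-region control
medians (a predictive-interval t with n−1 df). A one-tailed test is used
because the hypothesis is directional (hypermethylation). Degenerate
zero-variance inputs return 1 when means are equal and the limit (0 or 1)
otherwise.

Random control regions are contiguous probe windows matched to the target's
probe count within ±10% ("similar number of probes" is the only constraint
the design needs), disjoint from the target and each other, drawn with a
seeded generator. The matcher raises with the achieved count when the probe
map cannot supply enough windows.

## Consensus targets and EASE enrichment (`clustermir.targets`)

Sites match on (miRNA, 3'UTR, chrom, start, end) exactly; strand joins the
key only when both sources carry it (predictor exports disagree on whether
strand is reported). All intervals are 0-based half-open internally, and
1-based inclusive predictor dialects are converted at parse time; a
non-positive width after conversion aborts with a dialect error, which
catches mixed conventions early. Within-source duplicate rows are dropped
before matching. The exclusion rule is applied per (miRNA, UTR) pair: a pair
present in both sources with no coordinate-identical site is excluded
entirely; single-source pairs are simply absent, not "excluded".

The EASE statistic is the hypergeometric upper tail with one gene removed
from the overlap cell, margins unchanged: ease_p = P(X ≥ k−1) for
X ~ Hypergeom(universe, set, query). It is always ≥ the classical Fisher
one-tailed p, scores overlaps of 0 or 1 as exactly 1.0, and is monotone
non-increasing in the overlap. Sets below the minimum-overlap count (default
2) are omitted before correction. The default universe is every gene with at
least one predicted site in either source — the defensible in-house choice,
since external web-tool backgrounds are not reproducible — and is
configurable.

## qPCR (`clustermir.qpcr`)

Replicate wells are averaged per (sample, assay); spreads above 1 cycle (or
single wells) are flagged but retained — nothing is discarded silently.
ΔCt subtracts the mean of the sample's reference assays, so any sample-wide
loading shift cancels exactly. With several control samples the per-assay
baseline is the *mean* control ΔCt (median optional, not default). Fold
change is 2^(−ΔΔCt) with efficiency fixed at perfect doubling; no
standard-curve correction. Classification boundaries are inclusive —
fold change ≤ 0.6 is down, ≥ 2 up — because "at least 40% downregulation"
includes the 0.6 boundary itself. Per-assay calls average ΔΔCt across case
samples before converting; per-sample calls are also emitted for
heatmap-style reporting. Group significance uses the same Mann-Whitney
machinery as the expression module, applied to ΔCt values.

## Synthetic data (`clustermir.simulate`)

What it emulates: a miRnome-scale matrix (534 features, 38-member cluster by
default) with Gaussian per-feature baselines (mean 8, sd 2 log units),
Gaussian observation noise (sd 0.5), a planted cluster shift (−2 log units in
cases) and a background deregulated fraction (30% of non-cluster features,
split evenly up/down at the same magnitude); methylomes as Gaussian M-values
per region (hyper mean 2.5 ⇒ median β ≈ 0.85, background mean 0 ⇒ β ≈ 0.5,
sd 0.5, 200 probes per region, 12 disjoint regions across chromosomes); two
predictor site tables with exact planted counts of identical / discordant /
single-source (miRNA, UTR) pairs; and duplicate-well Ct tables with per-assay
base Cts, per-sample loading offsets, planted fold changes on case samples
(3+3 samples by default, well noise sd 0.15 cycles).

Default sample sizes (20+20) and effect sizes are chosen for comfortable
desk-scale power — separation of 4 noise-sd makes cluster recovery nearly
deterministic — not as estimates of tumour biology; the `gbm-like` CLI
preset switches to the 496/10 cohort dimensions. What it does *not* emulate:
array probe effects, batch structure, sequencing-depth or count noise,
correlated features, imprinting biology, plate effects in qPCR. Passing
tests therefore demonstrate that the *statistical machinery* is correct and
calibrated under its own assumptions, not that real cohorts will show these
effect sizes.

One global seed spawns independent per-stage child streams
(`numpy.random.SeedSequence`), so each stage regenerates identically whether
or not the others ran.

## Acceptance-script problem sizes

`scripts/acceptance.py` uses 200 global-null cohorts for calibration (chi
square rejection rate, binomial 2σ ≈ 0.03 at that count), 100 planted
cohorts for power, 50 simulated methylomes for region recovery, a 43-assay
synthetic qPCR panel (34 planted at fold change ≤ 0.6), and the planted
100/30/50 predictor tables — sizes at which every Monte-Carlo estimate is
stable to a few percent while the whole script stays in the seconds range.
The published-scale chi-square is computed directly on the printed 2×2
counts, which are inputs, not simulation outputs.

## Known limitations

* The chi-square on raw-call proportions is slightly conservative when the
  expected cluster down count is small (~2 at the global null); the
  calibration acceptance band (±0.03) absorbs this.
* Bonferroni over each one-tailed family separately controls each direction
  at α; the union of up- and down-false-calls is accordingly controlled at
  ~2α, which is inherent to directional calling with per-tail correction.
* Exact Mann-Whitney refuses ties (falls back to the approximation) rather
  than implementing a tie-aware enumeration.
* The EASE universe choice materially affects enrichment p-values; results
  should always report which universe was used.
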