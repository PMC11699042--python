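# Methods

## Problem and design

`straindrift` quantifies how much a cultured cancer cell line changes (a)
between independently propagated strains and (b) along long-term
continuous culture sampled at months 0, 6 and 12 (m0/m6/m12). The unit of
analysis is one cell line with one or more strains; each strain ×
timepoint state is observed through five assay layers: SNP genotyping
array calls, binned whole-genome copy-number log2 ratios, methylation
array intensity pairs, 3'-tag RNA count matrices (three biological
replicates), and resazurin drug screens (four replicate plates, ten-dose
series from 1e-5 to 10 µM, DMSO vehicle wells). Methylation is assayed in
two technical replicates.

Per layer the pipeline reduces the m12-vs-m0 comparison of the
continuously cultured strain to a single instability value, ranks cell
lines within a layer (ascending; average ranks on ties), and aggregates by
mean rank. The per-layer rankings are also reported separately, since a
numeric aggregation rule is a convenience, not part of the measurement.

## Layer metrics

**Genotype.** Calls are coded 0/1/2 with missing values. QC removes, in
order and attributing each locus to its first failing filter: call rate
≤ 0.95, Hardy–Weinberg exact p < 1e-6, chrY loci. The HWE test conditions
on allele counts and sums the probabilities of heterozygote counts no more
likely than the observed one (the standard exact test). HWE is computed on
the pooled strain set — these are not independent individuals, which is a
documented caveat of applying array QC defaults to cell lines. The
instability metric is the Euclidean distance between the m0 and m12
samples in the top-k (default k = 10, capped at matrix rank) PCA score
space of the locus-mean-imputed, column-centered dosage matrix. At full
rank this equals the distance between centered dosage rows; truncation
discards only low-variance directions. Concordance statistics
(shared-SNP fraction, transition counts) use complete cases: any locus
with a missing call in any strain is excluded from numerator and
denominator. Drift between dosage states is counted hom→het, het→hom, or
hom→hom-other.

**Copy number.** Tracks are 0-based half-open bins (BED convention);
segments are 1-based inclusive (SEG convention); converters keep the two
worlds separate. Segmentation is a simplified circular binary
segmentation: per chromosome, find the arc (i, j] maximizing the pooled
two-sample t² between inside and outside bins; accept the split when its
permutation p (default 1000 shuffles, seeded) falls below alpha = 0.01;
recurse into the pieces. No undo/pruning refinements are applied — the
downstream statistics need boundaries and segment means, not parity with
any particular reference implementation. Segment copy number is
2·2^(mean log2 ratio). The Genomic Index is
(#segments with |CN − 2| > 0.3)² / (#chromosomes carrying such a
segment), 0 when nothing is altered; the 0.3 tolerance is this package's
choice of "altered" on the CN scale. Cross-platform interval matching
requires same chromosome, positional overlap (r.start ≤ q.end and
r.end ≥ q.start), and query size within 80–120% of the reference size;
matched query CNs are averaged per reference. The CN-ratio area is the
trapezoidal integral of |log2(query/ref)| against interval midpoints on a
span-normalized genomic axis (identical profiles → 0; constant 2-fold
ratio → 1). The m12-vs-m0 instability metric segments both tracks,
assigns each bin its covering segment's CN, and computes that area.

**Methylation.** Per sample and per channel (methylated and unmethylated
corrected individually): subtract the 5th percentile of negative-control
intensities (lower order statistic, so the shifted controls' 5th
percentile is exactly 0 and the operation is idempotent), clip at 0, then
scale so the normalization-control mean is 10,000. β = M/(M+U+offset)
with offset 100; M-values are logit2(β) with β bounded into
[1e-6, 1−1e-6] so fully background-subtracted probes stay finite. Probes
in a user-supplied mask and on X/Y are flagged and excluded downstream;
mask lists are consumed as input, never bundled. Probe-wise differential
methylation is a two-group moderated t on M-values (see *Variance
moderation*), BH-adjusted, significant at FDR < 0.05, hypo- vs
hyper-methylated by the sign of ΔM. Separate two-group contrasts are run
per timepoint (m6 vs m0, m12 vs m0) rather than one pooled design.
Promoter-level analysis averages β over regions with ≥ 5 CpGs, tests the
logit2 of the region means with the same machinery, and a consistency
utility intersects significant regions across cell lines. Technical
replicates are treated as independent samples within a group — with two
replicates there is no other estimator of within-group variance; the
moderation pools information across probes to stabilize it.

**Transcriptome.** Genes with total count < 10 are dropped, then the
lowest 40% of the survivors by mean normalized expression. Size factors
are median-of-ratios over genes positive in every sample (upper-quartile
fallback otherwise). The differential test is a simplified
negative-binomial Wald: per-gene method-of-moments dispersion pooled
within groups, floored at the across-gene median (a crude dispersion
shrinkage — with 3 replicates the raw moment estimator is noisy enough
that lucky-low-variance genes would otherwise inflate the statistic), a
0.5 pseudo-mean protecting zero group means, and a normal Wald p on the
log2 mean ratio. DEG requires p_adj ≤ 0.01 and |log2FC| > 1. This
deliberately omits fold-change shrinkage and outlier filtering of
full-featured DE frameworks; a Welch t on log2 counts is available via
`moderated=False`-style options where exposed. CV profiles use the sample
(n−1) standard deviation over strain means, restricted to the top 60%
expressed genes, summarized per chromosome by the median. PCA operates on
centered log2(normalized + 1) of the 500 most variable genes. Paired
fold changes are log2((mean_m12 + 0.5)/(mean_m0 + 0.5)) per gene with
median/range summaries; each timepoint is normalized within itself, so
genuine global shifts survive (they are drift, not library size).

**Drug response.** Viability = signal / mean(DMSO wells of the same
plate). The AUC is the trapezoidal integral of viability (clipped to
[0, 1]; unclipped mode available for raw tracking) over log10
concentration divided by the log10 span: 1 = insensitive, 0 = fully
killed everywhere. Replicate rows at the same dose are averaged first. A
three-parameter Hill-fit AUC is available as an alternative; the
empirical trapezoid is the default. Strain variability: ED =
√Σ_c (mean AUC_c − AUC_strain,c)² per strain, summarized by the standard
error sd/√n across strains so entities with different strain counts stay
comparable; per-compound SE of AUC; pairwise Spearman ρ of AUC profiles
with the median off-diagonal entry as the headline similarity.
Fixed-dose viability reports the mean normalized viability at 1 µM
(nearest log-distance dose with a flag when absent). The m12-vs-m0
instability metric is |mean AUC_m12 − mean AUC_m0| / mean AUC_m0 across
compounds.

## Shared statistics

**BH adjustment** is the step-up procedure, supporting m ≥ #p-values so a
subset can be adjusted against the full test count.

**Wilcoxon tests.** The signed-rank test drops zero differences, assigns
average ranks to tied absolute differences, and enumerates the exact null
of W (sum of positive ranks) by convolution over doubled ranks for up to
25 nonzero pairs — the doubling makes half-integer average ranks integral,
so the exact path also covers ties. Beyond 25, a normal approximation
with tie-corrected variance Σr²/4 and a 0.5 continuity correction is
used. The rank-sum test uses the Mann–Whitney U with average ranks; the
exact null (Gaussian-binomial coefficients, built by exact integer
polynomial arithmetic) applies when min(n, m) ≤ 10 and the data are
tie-free, otherwise the tie-corrected normal approximation with
continuity correction. Two-sided p-values are 2·min(P(≥), P(≤)) capped at
1 in both tests. The cutoffs (25, 10) keep exact computation instant at
desk scale; both paths agree to < 0.01 where they overlap, and both tests
hold their nominal 5% level to within [0.04, 0.06] in the suite's
10,000-run null calibration.

**Variance moderation.** Per-unit variances s² with d residual df are
shrunken toward a prior (d0, s0²) fitted by method of moments on log s²
(digamma/trigamma matching): s²_post = (d0·s0² + d·s²)/(d0 + d), and the
moderated t uses d + d0 df. Negative excess spread of log s² means the
observed spread is at or below pure chi-square noise, so d0 = ∞ and every
posterior variance equals s0² (infinite df); literally identical inputs
shrink to themselves. Fewer than 10 units: no shrinkage (d0 = 0), with a
warning.

## The synthetic-data generator

The generator defines a parental state and evolves it:

- **loci** (default 20,000): allele frequencies ~ Beta(0.8, 0.8),
  genotypes binomial at those frequencies, ~40% in-exon, half of those
  non-synonymous; chromosomes from a compact karyotype (default 10
  autosomes × 40 one-Mb bins plus X and a short Y).
- **copy number**: 1–3 segments per chromosome, baseline CN ∈ {1, 2, 3}
  weighted toward 2.
- **CpGs** (default 10,000): bimodal baseline β from
  0.55·Beta(1.5, 15) + 0.45·Beta(15, 1.5); consecutive probes grouped
  into promoters of 2–8 CpGs (~70% of runs), leaving some regions below
  the 5-CpG analysis threshold on purpose.
- **genes** (default 5,000): lognormal base means, lognormal NB
  dispersions around 0.05.
- **compounds** (fixed library of 20): log10 IC50 ~ U(−3, 1), Hill slope
  ~ U(0.7, 2), floor viability ~ U(0, 0.3).

One culture interval = six months. Per interval: each locus flips between
adjacent dosage states (hom↔het) with probability `snp_flip_rate`
(default 0.002), so over n intervals a locus is touched with probability
1−(1−r)^n; a Poisson(`cn_event_rate`, default 1) number of whole-segment
±1 CN events (floored at 0); a `meth_drift_rate` (default 0.01) fraction
of CpGs shifted by N(0, `meth_shift_sd` = 2) on the M-value scale and
mapped back to β; an `expr_de_fraction` (default 0.02) of genes with
means multiplied by 2^N(0, `expr_lfc_sd` = 1.5); and every compound's
log10 IC50 shifted by N(0, `drug_potency_sd` = 0.15). Intervals compose:
evolving m0→m6→m12 equals evolving m0→m12 in distribution. The global
intensity knob `DriftConfig.scaled(f)` multiplies rates/fractions by f
(capped at 1) and the IC50 random-walk sd by √f — for a diffusion-like
process, intensity is variance per interval, and linear sd scaling would
let extreme lines walk clean out of the tested dose window, collapsing
the drug metric instead of growing it.

Rendering adds assay realism: genotype calls with 2% missingness; CN bins
log2(CN/2) + N(0, 0.15); methylation intensities with per-sample-channel
gains, a flat background of 200, lognormal total intensity around 10,000,
lognormal well noise, plus 100 negative and 100 normalization control
probes — constructed so that with noise off, normalization followed by
β = M/(M+U) recovers the state β exactly; expression counts
gamma-Poisson with per-replicate lognormal size factors; drug plates with
per-plate gains, Hill-curve signals on the 10-dose series and 8 DMSO
wells. Every draw comes from an RNG substream keyed by
(seed, layer, strain, timepoint, replicate), so adding strains or layers
never changes existing data.

The default five-line fixture orders drift line1 > … > line5 with
multipliers [40, 15, 6, 2.5, 1]. No quantitative drift rates are
available to emulate, so these are chosen for test power: the grid is
near-geometric, anchored at a base rate whose metrics sit above the assay
noise floor, and spaced widely enough that the single-realization noise
of one culture history per line rarely swaps adjacent lines. What passing
the recovery test shows is therefore that the pipeline orders lines
correctly when the generating separation is resolvable — not that
real cell lines are this separable.

What the generator does **not** emulate: clonal population structure and
selection (drift is memoryless per interval), linkage between loci,
probe-level chemistry beyond two control classes, batch structure across
samples (size factors and plate gains are independent draws), read-level
data, and drug interactions. Conclusions from synthetic tests transfer to
real data only insofar as the real assays match these independence
assumptions.

## Numerical choices and degenerate inputs

- Background percentile: lower order statistic (no interpolation), making
  normalization an exact fixed point under clipping.
- β bounds 1e-6 before any logit; β = 0 is representable (M = U = 0 with
  offset) but transforms finitely.
- Zero-variance arcs in segmentation: equal means → t² = 0 (no split);
  different means with zero within-arc variance → t² = ∞ (noiseless step
  splits exactly).
- Flat tracks, monomorphic loci, all-zero paired differences, constant
  correlation inputs, empty promoter sets, missing vehicle wells and
  zero baseline AUC all raise or warn explicitly rather than propagate
  NaN.
- Dispersion floor 1e-8; fold-change pseudo-mean 0.5; PCA top-gene count
  500; eigen-distance k = 10 (configurable; the choice is not critical
  because distances are dominated by the leading components).
- Ranking ties: average ranks; aggregate ties broken by the genotype
  layer, then lexicographically.

## Problem sizes in the test suite

The suite exercises the pipeline at reduced entity counts chosen as the
package's own test design: oracle checks on ≥ 100 random instances per
statistic; a full Hardy–Weinberg sweep of all genotype configurations
with n ≤ 50; 10,000-run Wilcoxon null calibrations at n = 20; 50-run
FDR/power calibrations at 10,000 probes (methylation) and 2,000 genes
(expression); segmentation recovery on 120-bin tracks (σ = 0.2, 3
breakpoints, 20 seeds); per-layer monotonicity over the drift grid
[1, 2.5, 6, 15, 40] with 20 seeds per point at 1,000 loci / 800 CpGs /
400 genes / 20 compounds; and 50 end-to-end ranking-recovery runs at
one-tenth entity scale (2,000 loci, 1,000 CpGs, 500 genes, 20 compounds).
The acceptance script uses the same scales.

## Known limitations

- The NB Wald test is intentionally simple; its null behavior is
  protected by the dispersion floor and the |log2FC| > 1 gate rather than
  by full empirical-Bayes dispersion and fold-change shrinkage.
- HWE on pooled cell-line strains is a filter, not a population-genetics
  inference.
- Batch correction is reduced to per-batch median-centering options;
  empirical-Bayes batch adjustment is out of scope.
- The CN-ratio area definition (|log2 ratio| vs normalized genomic
  position, trapezoid) is one reasonable concretization of an
  underdetermined summary; it is configurable and documented rather than
  canonical.
- Mean-rank aggregation is a presentation device; the per-layer rankings
  are the primary output.
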