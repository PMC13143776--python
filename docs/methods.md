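# Methods

`nelfyap` implements a desk-scale reanalysis pipeline for the question of how
the NELF pausing complex (via its NELFA subunit) constrains YAP-driven
transcription: four-condition knockdown differential expression, a
four-category co-regulation classifier, gene-set and overlap enrichment,
promoter-proximal pausing quantification from signal tracks, and clinical
IHC/survival stratification.  Every stage runs on synthetic inputs whose
statistical structure matches the assumptions of the corresponding analysis,
so the whole pipeline is testable without any external download.

## Differential expression stand-in

The DE stage is deliberately minimal.  Counts are normalized with
median-of-ratios size factors (per-gene reference = geometric mean across
samples; genes with any zero count excluded from the median; factors rescaled
to geometric mean 1).  For a contrast, the effect is

    log2FC = log2((mean normalized treated + 0.5) / (mean normalized control + 0.5))

with a 0.5 pseudocount keeping the estimate finite for zero-count genes.
Significance comes from a Wald statistic on the log2 scale.  The variance of
each group mean uses a method-of-moments negative-binomial model
Var = mu + alpha * mu^2, with alpha estimated per gene and pooled across the
two groups of the contrast; alpha is clamped at 0, which is exactly the
Poisson fallback when the sample variance does not exceed the mean.  The
statistic is referred to a t distribution with n1 + n2 - 2 degrees of
freedom rather than a normal: with three replicates per group the plug-in
variance is noisy, and the normal reference rejects ~11% of null genes at
the nominal 5% level while the t reference gives ~4-5% (KS distance from
uniform ~0.01 at 20k null genes).  Genes whose raw counts are identical
across both groups are assigned log2FC 0 and p 1 by convention.

Nothing beyond this is modelled: no dispersion shrinkage across genes, no
outlier handling, no independent filtering, no multiple-testing adjustment
(downstream gates use nominal p < 0.05, strict inequality, matching the
analysis this stage feeds).  The stage's correctness criterion is
planted-effect recovery and null calibration on simulated data, not
agreement with any particular DE package.

## Co-regulation classifier

Genes are classified from the triple (fc_N, fc_Y, fc_D) of log2 fold changes
in the siNELFA, siYAP and double-knockdown contrasts:

| category | fc_N | fc_Y | fc_D |
|---|---|---|---|
| NELFA-suppressed / YAP-activated | >= +1 | <= -1 | -1 < fc_D < +1 |
| NELFA-activated / YAP-suppressed | <= -1 | >= +1 | -1 < fc_D < +1 |
| co-suppressed | >= +1 | >= +1 | fc_D >= max(fc_N, fc_Y) |
| co-activated | <= -1 | <= -1 | fc_D <= min(fc_N, fc_Y) |

Boundary conventions: non-strict on the single-knockdown thresholds, strict
on the double-knockdown interior for the antagonistic categories.  For the
co-regulated categories the double-knockdown condition is "at least as
extreme as the more extreme single knockdown"; no additional bound on fc_D
is imposed (an extra `-1 <` clause would contradict the `>= max` condition
whenever both singles exceed +1, so only the extremity condition is kept).
The four predicates are mutually exclusive — verified exhaustively on a
9-point grid per axis — and negating all three inputs swaps category 1 with
2 and 3 with 4.

Classification is gated: a gene must have nominal p < alpha in *both*
single-knockdown contrasts.  This is the weakest gate under which all four
categories are observable; gating on all three contrasts would exclude
categories 1-2, whose defining feature is a near-null double knockdown.

## Enrichment

Pre-ranked GSEA uses the weighted Kolmogorov-Smirnov running sum: genes are
ranked by log2FC (descending, significant genes only, ties broken by gene
id); walking the ranking, hits add |score|^w normalized by total hit weight
(w = 1 by default, the classic "weighted" statistic) and misses subtract
1/(N - n_hits); ES is the signed maximum deviation.  The null is
gene-sampling: random same-size sets drawn from the ranked universe
(replicate-level phenotype permutation is impossible after the DE stage
collapses replicates).  NES divides ES by the mean |null ES| of matching
sign; the nominal p is (1 + #{same-sign null at least as extreme}) /
(1 + #same-sign null), so the minimum attainable p is 1/(1 + n_same) and p
is never 0.  Sets are filtered to 5-500 members after intersection with the
ranked universe.  Enrichr-style combined scores are not computed; overlap
enrichment reports the overlap count, the one-sided Fisher exact p (equal to
the hypergeometric tail) and the odds ratio ad/bc with a Haldane +0.5
correction on all cells when any cell is zero.

## Promoter-proximal pausing

All genomic intervals are 0-based half-open.  Per gene the longest
transcript is kept (ties: lexicographically smallest transcript id).  The
TSS is the first transcribed base (start on +, end-1 on -).  The promoter
window is [TSS-150, TSS+150) — 300 bp, strand-symmetric, so strand does not
affect it.  The gene-body window is 2000 bp running downstream along the
direction of transcription: [TSS+250, TSS+2250) on +, [TSS-2250+1,
TSS-250+1) on -, because nascent-transcription signal measures elongation
downstream of the TSS.

Promoter occupancy is log2((mean ChIP + eps)/(mean input + eps)) over the
promoter window with eps = 1e-3 guaranteeing finiteness; window means count
uncovered bases as zero coverage (standard coverage-track semantics); a sum
summary is available by flag.  Gene-body output is the mean of the plus- and
minus-strand nascent signal *summed* (not averaged) over the window.

Genes with baseline occupancy > 0.5 (about 1.4-fold over input) are
retained.  Among retained genes, "complete loss" of occupancy is
operationalized as the perturbed enrichment falling below half the baseline
log2 enrichment.  A relative rule was chosen deliberately: reference
quantifications of genes with reported coordinated loss include promoters
dropping from 2.82 to 0.99 log2 units — a 3.6-fold occupancy collapse that
an absolute floor at the retention threshold would miss — alongside weakly
bound promoters dropping from 0.57 to 0.03.  Losing more than half the
baseline enrichment captures both regimes with one parameter; an absolute
floor (`loss_threshold`) remains available.  Loss together with any output
increase is `coordinated_loss_up` (no minimum fold change by default — the
reference set includes increases as small as 0.76 -> 0.77; a `min_fold`
parameter exists); retained genes with decreased output are `output_down`,
the rest `unchanged`.

## Clinical analyses

Percent-positive IHC staining is binned 0% -> 0, 1-10% -> 1, 11-50% -> 2,
51-100% -> 3 and multiplied by a 0-3 intensity (a standard IHC intensity
scale), giving a composite score in {0..9}.  The high/low cutoff maximizes
Youden's J over midpoints between consecutive distinct observed scores,
against the DFS event indicator over the full follow-up (event status only;
time-to-event ROC was not used).  Ties in J break toward the smaller
cutoff; "high" means score >= cutoff.  For expression-based cohorts the
split is at the sample median with values equal to the median labelled low.

Survival uses the Kaplan-Meier product-limit estimator and the Mantel-Cox
log-rank test (observed-vs-expected events with hypergeometric variance,
chi-square reference with groups-1 degrees of freedom), both through
lifelines.  Categorical associations use the uncorrected Pearson chi-square
test: the published cohort tables this package recomputes are only
reproduced without the Yates continuity correction (e.g. the 2x2 grade
table [[24,13],[14,20]] gives chi-square 4.00, p 0.0456 uncorrected),
which pins down the test variant.  Missing covariates are excluded
per-test (pairwise deletion).

## Synthetic data

The generators are pure functions of their arguments including the seed.

**Counts** — 4 conditions x 3 replicates; baseline means log-uniform on
[20, 2000]; counts negative-binomial with Var = mu + alpha*mu^2, alpha =
0.05 constant across genes.  Planted genes (50 per category by default)
multiply condition means by 2^±2 according to their category's sign
pattern.  Co-regulated doubles use 2x the larger single multiplier: the
double-vs-single fold-change comparison has ~0.33 log2 units of estimation
noise at 3 replicates and dispersion 0.05 (the control term cancels, leaving
two group-mean variances), so a margin of one log2 unit (~3 sd) is the
smallest round value that makes planted categories recoverable rather than
coin-flip at the boundary; at 1.25x (0.32 log2 units, ~1 sd) categories 3-4
were recovered at only ~70-78%.

**Tracks** — one toy chromosome, transcripts tiled every 10 kb, 5 kb long,
alternating strands, so every window fits.  Input is flat 1.0; bound
promoters (80% of genes) carry a 4-fold ChIP peak; loss-flagged genes (50%
of bound) lose the peak entirely in the perturbed state and gain 1.3-fold
output; half the remaining bound genes lose 1.3-fold output.  Tracks are
noiseless by construction: the pausing caller is required to match the truth
table *exactly*, which a noisy generator could not demand.

**Cohort** — subtype mixture 41/27/32% (ER+/HER2+/TNBC); marker percents
from a two-component mixture (low U(0,10), high U(40,100), equal weights);
intensities uniform on {1,2,3}; survival exponential with per-joint-group
monthly hazards (defaults 0.020/0.012/0.006/0.004, worst for double-high,
giving ~70% vs ~21% five-year event probability); censoring administrative
at 60 months combined with uniform dropout on (0, 180) months.  Calibration
simulations (type-I error, power) dichotomize by the true YAP state —
two-group log-rank — because with ~30 events per 100-patient cohort the
four-group chi-square reference is visibly liberal (6.6% vs 5.2% empirical
size at the nominal 5%).

What the generators do *not* emulate: library-size heterogeneity beyond
size-factor scaling, gene-gene correlation, batch effects, read-level noise
in tracks, fragment-length effects, informative censoring, covariate-
dependent marker expression.  Passing tests therefore demonstrate
correctness of the statistical machinery under its own assumptions, not
robustness to real-data pathologies.

## Problem sizes

Simulation-based checks use 2200 genes (200 planted), 150-200 track genes,
cohorts of 75-200 patients, 1000 null cohorts for test-size calibration,
300 cohorts for power, and 1000 GSEA permutations — sizes at which every
Monte-Carlo margin in the tests is several standard errors wide while the
full suite and the acceptance script each run in well under a minute of
compute per stage.

## Known limitations

- The DE stand-in is anti-conservative for very low counts (< ~5 per group)
  where the delta-method variance on the log2 scale degrades; the simulation
  floor of 20 keeps tests away from that regime, real data would not.
- The gene-sampling GSEA null ignores gene-gene correlation, as does every
  pre-ranked implementation of this statistic.
- The ROC cutoff uses the event indicator, ignoring censoring times; with
  heavy early censoring this biases the cutoff.
- `overlap_counts` enumerates all 2^k - 1 Venn regions and is intended for
  k <= 4 sets.
- BigWig input is supported only when pyBigWig is installed; bedGraph is the
  canonical, bit-exact surface.
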