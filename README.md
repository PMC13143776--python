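# nelfyap

Analysis pipeline for NELFA–YAP co-regulation in breast cancer: how the NELF
promoter-proximal pausing complex constrains YAP-driven transcription, and
what the two markers jointly mean for patient outcomes.

The package is aimed at computational biologists who want to re-run, test or
extend the statistical machinery of this kind of study — four-condition
knockdown differential expression, co-regulation classification, enrichment,
pausing quantification from signal tracks, and IHC/survival stratification —
without needing the original sequencing data: a synthetic-data module
generates inputs with the right statistical structure, plus truth tables for
scoring every caller.

## What it computes

- **Differential expression** (`nelfyap.diffexpr`) — a minimal, documented
  count-based DE stage: median-of-ratios size factors, log2FC with a 0.5
  pseudocount, and a Wald test with a method-of-moments negative-binomial
  variance, for the three contrasts siNELFA, siYAP and siNELFA+siYAP, each
  vs siControl.
- **Co-regulation classifier** (`nelfyap.coregulation`) — assigns each gene
  to one of four mutually exclusive categories from its fold-change triple
  (fc_N, fc_Y, fc_D): NELFA-suppressed/YAP-activated (fc_N ≥ +1, fc_Y ≤ −1,
  −1 < fc_D < +1), its mirror, co-suppressed (both ≥ +1 and fc_D ≥ max),
  co-activated (both ≤ −1 and fc_D ≤ min); plus exact Venn region counts
  for 2–4 gene sets.
- **Enrichment** (`nelfyap.enrichment`) — pre-ranked GSEA (weighted
  Kolmogorov–Smirnov running-sum ES, gene-sampling NES and nominal p) and
  one-sided Fisher-exact overlap enrichment with odds ratios.
- **Pausing** (`nelfyap.pausing`) — promoter windows TSS ± 150 bp and
  strand-directional gene bodies TSS+250..TSS+2250; log2(ChIP/input)
  occupancy; strand-combined nascent output; retention filter at
  log2 enrichment > 0.5; coordinated loss-with-output-increase calls.
- **Clinical** (`nelfyap.clinical`) — composite IHC scores (binned percent ×
  intensity), ROC/Youden cutoffs, median splits, Kaplan–Meier curves,
  Mantel–Cox log-rank tests, and uncorrected Pearson chi-square contingency
  tests.
- **Synthetic data** (`nelfyap.synthdata`) — negative-binomial counts with
  planted categories, noiseless promoter-peaked tracks with planted
  occupancy loss, and cohorts with group-specific exponential survival.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the numbered drivers in `analysis/` (each is a thin wrapper over the
library and writes its tables under `results/run/`), or the equivalent CLI
(`nelfyap all --seed 1 --outdir results/run`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/03_classify_coregulation.py --seed 1
```

```
simulated 2200 genes x 12 samples, 200 track genes, 200 patients, 8 gene sets -> results/run/
classified 2200 genes:
  NELFA_activated_YAP_suppressed: 49
  NELFA_suppressed_YAP_activated: 50
  co_activated: 47
  co_suppressed: 50
  none: 2004
planted-category recovery: 98.0% of 200 planted genes
```

Fifty genes per category were planted with 4-fold effects; the DE stage plus
classifier recovers 196/200 of them with zero false categories among the
2000 null genes.  The pausing driver shows the track side:

```sh
python analysis/05_pausing_quantification.py --seed 1
```

```
quantified 200 genes; calls:
  coordinated_loss_up: 83
  not_retained: 48
  unchanged: 35
  output_down: 34
coordinated_loss_up calls matching planted truth: 100.0%
```

and `analysis/07_reference_tables.py` recomputes the published cohort
statistics bundled with the package, e.g. the grade-by-subtype table gives
chi-square 14.63 (df 2, p = 0.0007) and all seven NELF-C degron reference
genes are called `coordinated_loss_up` (HEG1: occupancy 2.66 → −0.004 with
output 0.76 → 0.77).

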