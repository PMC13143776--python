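"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators emulate the three input classes the pipeline consumes:

* negative-binomial counts for the four-condition knockdown design
  (4 conditions x 3 replicates by default) with genes planted in the four
  co-regulation categories,
* noiseless promoter-peaked ChIP/input tracks plus uniform strand-specific
  gene-body nascent signal over a toy genome, with planted occupancy loss and
  output changes,
* a breast-cancer-like cohort with subtype mixture, bimodal IHC marker
  scores, and exponential survival with group-specific monthly hazards under
  administrative censoring plus uniform dropout.

Every generator is a pure function of its arguments including ``seed`` and
returns a truth table sufficient to score the downstream callers.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    CONDITIONS,
    SUBTYPES,
    ClinicalRecord,
    CountMatrix,
    SignalTrack,
    TranscriptModel,
)

CATEGORY_NAMES = (
    "NELFA_suppressed_YAP_activated",
    "NELFA_activated_YAP_suppressed",
    "co_suppressed",
    "co_activated",
)

#: Default joint-marker monthly hazards: worst outcome for double-high
#: expression, mirroring the ordering reported for the IHC cohort.
DEFAULT_GROUP_HAZARDS = {
    "HighYAP_HighNELFA": 0.020,
    "HighYAP_LowNELFA": 0.012,
    "LowYAP_HighNELFA": 0.006,
    "LowYAP_LowNELFA": 0.004,
}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    n_genes: int,
    n_planted_per_category: int = 50,
    effect_log2fc: float = 2.0,
    reps: int = 3,
    dispersion: float = 0.05,
    seed: int = 0,
    mean_range: tuple[float, float] = (20.0, 2000.0),
    double_margin: float = 2.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the four-condition knockdown count matrix with planted genes.

    Planted genes receive condition-specific mean multipliers implementing the
    sign pattern of their category: category 1 is up in siNELFA and down in
    siYAP with no change in the double knockdown; category 2 is the mirror;
    categories 3/4 move the same way in both singles and further in the double
    (multiplier ``double_margin`` times the larger single multiplier).  The
    default margin of 2x (one extra log2 unit, about three standard
    deviations of the fold-change comparison at 3 replicates and dispersion
    0.05) guarantees the most-extreme-in-double condition survives estimation
    noise.  Null genes share one mean
    across conditions.  Baseline means are log-uniform over ``mean_range``.

    Returns the matrix and a truth table (gene_id, category, true log2 effect
    per contrast).
    """
    if n_genes < 4 * n_planted_per_category:
        raise ValueError("n_genes must be at least 4 * n_planted_per_category")
    if reps < 2:
        raise ValueError("at least 2 replicates per condition are required")
    if effect_log2fc < 1:
        warnings.warn(
            "effect_log2fc < 1 will not satisfy the category thresholds by construction",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_genes))

    up, down = 2.0 ** effect_log2fc, 2.0 ** -effect_log2fc
    # per-category multipliers for (siNELFA, siYAP, siNELFA_siYAP)
    cat_mult = {
        CATEGORY_NAMES[0]: (up, down, 1.0),
        CATEGORY_NAMES[1]: (down, up, 1.0),
        CATEGORY_NAMES[2]: (up, up, double_margin * up),
        CATEGORY_NAMES[3]: (down, down, down / double_margin),
    }
    categories = np.array(["none"] * n_genes, dtype=object)
    for k, name in enumerate(CATEGORY_NAMES):
        lo = k * n_planted_per_category
        categories[lo : lo + n_planted_per_category] = name

    mult = np.ones((n_genes, len(CONDITIONS)))
    for i, cat in enumerate(categories):
        if cat != "none":
            mult[i, 1:] = cat_mult[cat]

    cols, data = [], []
    sheet_rows = []
    for j, cond in enumerate(CONDITIONS):
        means = base * mult[:, j]
        for r in range(1, reps + 1):
            sid = f"{cond}_r{r}"
            cols.append(sid)
            sheet_rows.append({"sample_id": sid, "condition": cond, "replicate": r})
            data.append(_nb_draw(rng, means, dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "category": categories,
            "true_lfc_siNELFA": np.log2(mult[:, 1]),
            "true_lfc_siYAP": np.log2(mult[:, 2]),
            "true_lfc_siNELFA_siYAP": np.log2(mult[:, 3]),
        }
    )
    return CountMatrix(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def make_toy_transcripts(
    n_genes: int,
    chrom: str = "chrS",
    spacing: int = 10_000,
    length: int = 5_000,
    offset: int = 2_500,
) -> list[TranscriptModel]:
    """Tile non-overlapping transcripts along one toy chromosome.

    Defaults (10 kb spacing, 5 kb length, 2.5 kb leading offset) guarantee the
    promoter (TSS +/- 150 bp) and gene-body (TSS+250..TSS+2250) windows fit for
    either strand.  Strands alternate.
    """
    out = []
    for i in range(n_genes):
        start = offset + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        out.append(
            TranscriptModel(chrom, start, start + length, strand, f"tg{i:04d}", f"tt{i:04d}")
        )
    return out


def _piecewise(chrom: str, length: int, segments: list[tuple[int, int, float]], base: float) -> SignalTrack:
    """Build a track that is ``base`` everywhere except the given segments."""
    segments = sorted(segments)
    starts, ends, values = [], [], []
    pos = 0
    for s, e, v in segments:
        if s > pos and base != 0.0:
            starts.append(pos), ends.append(s), values.append(base)
        starts.append(s), ends.append(e), values.append(v)
        pos = e
    if pos < length and base != 0.0:
        starts.append(pos), ends.append(length), values.append(base)
    return SignalTrack({chrom: (np.array(starts), np.array(ends), np.array(values))})


def simulate_tracks(
    transcripts: Sequence[TranscriptModel],
    bound_fraction: float = 0.8,
    loss_fraction: float = 0.5,
    peak_enrichment: float = 4.0,
    output_fold: float = 1.3,
    seed: int = 0,
    promoter_halfwidth: int = 150,
    body_offset: tuple[int, int] = (250, 2250),
) -> tuple[dict[str, SignalTrack], pd.DataFrame]:
    """Simulate noiseless ChIP/input/nascent tracks over a toy genome.

    The input track is flat at 1.0.  Baseline ChIP equals input times
    ``peak_enrichment`` over each bound promoter and input elsewhere; the
    perturbed ChIP removes the peak for loss-flagged genes.  Nascent signal is
    uniform at 1.0 over gene bodies on the transcript's strand and is
    multiplied by ``output_fold`` (direction ``up``) or divided by it
    (direction ``down``) in the perturbed state.  Loss-flagged genes are
    assigned direction ``up``; half of the remaining bound genes ``down``, the
    rest unchanged.

    Returns a dict of tracks keyed ``input``, ``chip_baseline``,
    ``chip_perturbed``, ``nascent_{plus,minus}_{baseline,perturbed}`` and the
    per-transcript truth table.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    rng = np.random.default_rng(seed)
    chrom = transcripts[0].chrom
    genome_end = max(t.end for t in transcripts) + 10_000

    kept: list[TranscriptModel] = []
    for t in transcripts:
        body_len = body_offset[1] - body_offset[0]
        if t.length < body_offset[1] or t.tss - promoter_halfwidth < 0 or body_len <= 0:
            warnings.warn(f"transcript {t.transcript_id} too short for windows; skipped")
            continue
        kept.append(t)

    n = len(kept)
    bound = rng.random(n) < bound_fraction
    loss = bound & (rng.random(n) < loss_fraction)
    direction = np.array(["none"] * n, dtype=object)
    direction[loss] = "up"
    residual = np.flatnonzero(bound & ~loss)
    down_idx = residual[rng.random(len(residual)) < 0.5]
    direction[down_idx] = "down"

    prom_peaks_base, prom_peaks_pert = [], []
    plus_base, plus_pert, minus_base, minus_pert = [], [], [], []
    for i, t in enumerate(kept):
        prom = (t.tss - promoter_halfwidth, t.tss + promoter_halfwidth)
        if t.strand == "+":
            body = (t.tss + body_offset[0], t.tss + body_offset[1])
        else:
            body = (t.tss - body_offset[1] + 1, t.tss - body_offset[0] + 1)
        if bound[i]:
            prom_peaks_base.append((prom[0], prom[1], peak_enrichment))
            if not loss[i]:
                prom_peaks_pert.append((prom[0], prom[1], peak_enrichment))
        fold = {"up": output_fold, "down": 1.0 / output_fold, "none": 1.0}[direction[i]]
        seg_base = (body[0], body[1], 1.0)
        seg_pert = (body[0], body[1], fold)
        if t.strand == "+":
            plus_base.append(seg_base), plus_pert.append(seg_pert)
        else:
            minus_base.append(seg_base), minus_pert.append(seg_pert)

    tracks = {
        "input": _piecewise(chrom, genome_end, [], 1.0),
        "chip_baseline": _piecewise(chrom, genome_end, prom_peaks_base, 1.0),
        "chip_perturbed": _piecewise(chrom, genome_end, prom_peaks_pert, 1.0),
        "nascent_plus_baseline": _piecewise(chrom, genome_end, plus_base, 0.0),
        "nascent_minus_baseline": _piecewise(chrom, genome_end, minus_base, 0.0),
        "nascent_plus_perturbed": _piecewise(chrom, genome_end, plus_pert, 0.0),
        "nascent_minus_perturbed": _piecewise(chrom, genome_end, minus_pert, 0.0),
    }
    truth = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in kept],
            "transcript_id": [t.transcript_id for t in kept],
            "bound": bound,
            "occupancy_loss": loss,
            "output_direction": direction,
        }
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    n: int = 75,
    subtype_props: Sequence[float] = (0.41, 0.27, 0.32),
    group_hazards: Mapping[str, float] | None = None,
    censor_months: float = 60.0,
    seed: int = 0,
    dropout_scale: float = 3.0,
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Simulate an IHC-scored cohort with group-specific exponential survival.

    Marker percents come from a two-component mixture (low: U(0,10); high:
    U(40,100); equal weights) per marker; intensities are uniform on {1,2,3}.
    The true risk group is the joint high/low state of the two markers and
    sets the monthly hazard of the exponential event time.  Censoring is
    administrative at ``censor_months`` combined with uniform dropout on
    (0, dropout_scale * censor_months).  DFS times are drawn independently
    with the same group hazard.
    """
    if n < 20:
        raise ValueError("cohort size must be at least 20")
    props = np.asarray(subtype_props, dtype=float)
    if props.min() < 0 or not np.isclose(props.sum(), 1.0):
        raise ValueError("subtype proportions must be non-negative and sum to 1")
    hazards = dict(group_hazards or DEFAULT_GROUP_HAZARDS)
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)

    subtype = rng.choice(list(SUBTYPES), size=n, p=props)
    records, truth_rows = [], []
    for i in range(n):
        state = {}
        scores = {}
        for marker in ("YAP", "NELFA"):
            high = rng.random() < 0.5
            percent = rng.uniform(40, 100) if high else rng.uniform(0, 10)
            intensity = int(rng.integers(1, 4))
            state[marker] = "High" if high else "Low"
            scores[marker] = (percent, intensity)
        group = f"{state['YAP']}YAP_{state['NELFA']}NELFA"
        lam = hazards[group]

        def draw_endpoint() -> tuple[float, int]:
            t_event = rng.exponential(1.0 / lam)
            if censor_months <= 0:
                return 0.0, 0
            c = min(censor_months, rng.uniform(0, dropout_scale * censor_months))
            return (t_event, 1) if t_event <= c else (c, 0)

        os_t, os_e = draw_endpoint()
        dfs_t, dfs_e = draw_endpoint()
        records.append(
            ClinicalRecord(
                patient_id=f"p{i:04d}",
                subtype=str(subtype[i]),
                yap_percent=scores["YAP"][0],
                nelfa_percent=scores["NELFA"][0],
                yap_intensity=scores["YAP"][1],
                nelfa_intensity=scores["NELFA"][1],
                os_months=os_t,
                dfs_months=dfs_t,
                os_event=os_e,
                dfs_event=dfs_e,
            )
        )
        truth_rows.append(
            {"patient_id": f"p{i:04d}", "risk_group": group, "hazard": lam}
        )
    return records, pd.DataFrame(truth_rows)
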