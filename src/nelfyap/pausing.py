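"""Promoter-proximal pausing: windows, occupancy, output, coordinated calls.

Per gene, the longest transcript defines a TSS.  The promoter window is
TSS +/- 150 bp (300 bp, strand-independent); the gene-body window is
TSS+250..TSS+2250 downstream along the direction of transcription (2 kb).
Promoter occupancy is log2((mean ChIP + eps)/(mean input + eps)) over the
promoter window; transcriptional output is the mean of the plus- and
minus-strand nascent signal summed over the gene-body window.

Genes with baseline occupancy > 0.5 (about 1.4-fold over input) are retained.
Among retained genes, a *coordinated loss* call requires the perturbed state
to lose the promoter peak — operationalized as perturbed occupancy falling
below half the baseline log2 enrichment (an absolute floor can be supplied
instead) — together with increased gene-body output; retained genes whose
output decreases are called ``output_down``, all others ``unchanged``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import SignalTrack, TranscriptModel

RETENTION_THRESHOLD = 0.5
PROMOTER_HALFWIDTH = 150
BODY_OFFSET = (250, 2250)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int


def select_longest_transcript(ts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Per gene, the longest transcript; ties by smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for t in ts:
        cur = best.get(t.gene_id)
        # longer wins; at equal length the lexicographically smaller id wins
        if cur is None or t.length > cur.length or (
            t.length == cur.length and t.transcript_id < cur.transcript_id
        ):
            best[t.gene_id] = t
    return [best[g] for g in sorted(best)]


def make_windows(t: TranscriptModel) -> tuple[Window, Window]:
    """Promoter and gene-body windows for one transcript.

    The promoter is symmetric about the TSS; the gene body runs downstream
    along the direction of transcription.  Raises if either window would
    extend below coordinate 0.
    """
    tss = t.tss
    promoter = Window(t.chrom, tss - PROMOTER_HALFWIDTH, tss + PROMOTER_HALFWIDTH)
    if t.strand == "+":
        body = Window(t.chrom, tss + BODY_OFFSET[0], tss + BODY_OFFSET[1])
    else:
        body = Window(t.chrom, tss - BODY_OFFSET[1] + 1, tss - BODY_OFFSET[0] + 1)
    for w in (promoter, body):
        if w.start < 0:
            raise ValueError(
                f"window out of bounds for {t.transcript_id}: starts at {w.start}"
            )
    return promoter, body


def promoter_enrichment(
    chip: SignalTrack, input_track: SignalTrack, w: Window, eps: float = 1e-3
) -> float:
    """log2((mean ChIP + eps) / (mean input + eps)) over the promoter window."""
    c = chip.mean(w.chrom, w.start, w.end)
    i = input_track.mean(w.chrom, w.start, w.end)
    return float(np.log2((c + eps) / (i + eps)))


def genebody_output(plus: SignalTrack, minus: SignalTrack, w: Window) -> float:
    """Mean of plus+minus nascent signal over the gene-body window."""
    return plus.mean(w.chrom, w.start, w.end) + minus.mean(w.chrom, w.start, w.end)


def quantify(
    transcripts: Sequence[TranscriptModel],
    chip_baseline: SignalTrack,
    chip_perturbed: SignalTrack,
    input_track: SignalTrack,
    nascent_plus_baseline: SignalTrack,
    nascent_minus_baseline: SignalTrack,
    nascent_plus_perturbed: SignalTrack,
    nascent_minus_perturbed: SignalTrack,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene promoter occupancy and gene-body output in both states.

    Transcripts are reduced to one per gene (longest) first.
    """
    rows = []
    for t in select_longest_transcript(transcripts):
        prom, body = make_windows(t)
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "promoter_enrichment_baseline": promoter_enrichment(
                    chip_baseline, input_track, prom, eps
                ),
                "promoter_enrichment_perturbed": promoter_enrichment(
                    chip_perturbed, input_track, prom, eps
                ),
                "genebody_output_baseline": genebody_output(
                    nascent_plus_baseline, nascent_minus_baseline, body
                ),
                "genebody_output_perturbed": genebody_output(
                    nascent_plus_perturbed, nascent_minus_perturbed, body
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def call_pausing(
    records: pd.DataFrame,
    retention_threshold: float = RETENTION_THRESHOLD,
    loss_fraction: float = 0.5,
    loss_threshold: float | None = None,
    min_fold: float | None = None,
) -> pd.DataFrame:
    """Retention filtering and coordinated-change calls.

    ``records`` needs the four quantification columns produced by
    :func:`quantify`.  Genes with baseline occupancy <= ``retention_threshold``
    are ``not_retained``.  Among retained genes, occupancy loss means the
    perturbed enrichment fell below ``loss_fraction`` of baseline (or below
    the absolute ``loss_threshold`` if one is given); loss together with an
    output increase is ``coordinated_loss_up``; otherwise a decreased output
    is ``output_down`` and anything else ``unchanged``.  ``min_fold`` imposes
    an optional minimum fold change on the output comparison (default: any
    change counts).
    """
    needed = [
        "promoter_enrichment_baseline",
        "promoter_enrichment_perturbed",
        "genebody_output_baseline",
        "genebody_output_perturbed",
    ]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise KeyError(f"missing quantification columns: {missing}")
    if records[needed].isna().any().any():
        raise ValueError("gene present in only one state (NaN quantification)")

    base = records["promoter_enrichment_baseline"].to_numpy()
    pert = records["promoter_enrichment_perturbed"].to_numpy()
    out_b = records["genebody_output_baseline"].to_numpy()
    out_p = records["genebody_output_perturbed"].to_numpy()

    retained = base > retention_threshold
    if loss_threshold is not None:
        lost = pert < loss_threshold
    else:
        lost = pert < loss_fraction * base
    fold = min_fold if min_fold is not None else 1.0
    up = out_p > fold * out_b
    down = out_p * fold < out_b

    call = np.where(
        ~retained,
        "not_retained",
        np.where(lost & up, "coordinated_loss_up", np.where(down, "output_down", "unchanged")),
    )
    out = records.copy()
    out["retained_baseline"] = retained
    out["call"] = call
    return out
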