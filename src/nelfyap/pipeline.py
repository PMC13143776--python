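"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: simulate -> de -> classify -> enrich ->
pausing -> clinical.  Every stage reads and writes files in the run directory
through the :mod:`nelfyap.dataio` formats, so any stage can be re-run or
resumed in isolation; a manifest records the config hash, seeds, package
version and per-stage row counts.  All randomness flows from the named seeds
in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinical as clin
from . import coregulation, diffexpr, enrichment, pausing, synthdata
from .dataio import (
    read_clinical,
    read_counts,
    read_gene_sets,
    read_track,
    read_transcripts,
    write_clinical,
    write_counts,
    write_gene_sets,
    write_rnk,
    write_track,
    write_transcripts_bed,
    GeneSetCollection,
)

log = logging.getLogger("nelfyap")

STAGES = ("simulate", "de", "classify", "enrich", "pausing", "clinical")

TRACK_NAMES = (
    "input",
    "chip_baseline",
    "chip_perturbed",
    "nascent_plus_baseline",
    "nascent_minus_baseline",
    "nascent_plus_perturbed",
    "nascent_minus_perturbed",
)


@dataclass
class RunConfig:
    """All knobs of the pipeline with their documented defaults."""

    outdir: str = "runs/synthetic"
    simulate: bool = True
    seed: int = 0
    alpha: float = 0.05

    # synthetic count matrix
    n_genes: int = 2200
    n_planted_per_category: int = 50
    effect_log2fc: float = 2.0
    reps: int = 3
    dispersion: float = 0.05

    # synthetic tracks
    n_track_genes: int = 200
    bound_fraction: float = 0.8
    loss_fraction: float = 0.5
    peak_enrichment: float = 4.0
    output_fold: float = 1.3

    # synthetic cohort
    cohort_n: int = 200
    censor_months: float = 60.0

    # GSEA
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500

    # pausing
    pausing_eps: float = 1e-3
    retention_threshold: float = 0.5
    pausing_loss_fraction: float = 0.5

    # external inputs (used when simulate is False)
    counts_path: str | None = None
    samples_path: str | None = None
    transcripts_path: str | None = None
    gene_sets_path: str | None = None
    clinical_path: str | None = None
    tracks_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _out(config: RunConfig, name: str) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p / name


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> dict:
    if not config.simulate:
        for name, path in (
            ("counts", config.counts_path),
            ("sample sheet", config.samples_path),
        ):
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing input: {name} ({path})")
        log.info("simulate stage skipped (external inputs)")
        return {"skipped": True}

    m, truth = synthdata.simulate_counts(
        n_genes=config.n_genes,
        n_planted_per_category=config.n_planted_per_category,
        effect_log2fc=config.effect_log2fc,
        reps=config.reps,
        dispersion=config.dispersion,
        seed=config.stage_seed("counts"),
    )
    write_counts(m, _out(config, "counts.tsv"), _out(config, "samples.csv"))
    truth.to_csv(_out(config, "counts_truth.tsv"), sep="\t", index=False)

    transcripts = synthdata.make_toy_transcripts(config.n_track_genes)
    write_transcripts_bed(transcripts, _out(config, "transcripts.bed"))
    tracks, track_truth = synthdata.simulate_tracks(
        transcripts,
        bound_fraction=config.bound_fraction,
        loss_fraction=config.loss_fraction,
        peak_enrichment=config.peak_enrichment,
        output_fold=config.output_fold,
        seed=config.stage_seed("tracks"),
    )
    tracks_dir = Path(config.outdir) / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    for name in TRACK_NAMES:
        write_track(tracks[name], tracks_dir / f"{name}.bedGraph")
    track_truth.to_csv(_out(config, "tracks_truth.tsv"), sep="\t", index=False)

    records, cohort_truth = synthdata.simulate_cohort(
        n=config.cohort_n,
        censor_months=config.censor_months,
        seed=config.stage_seed("cohort"),
    )
    write_clinical(records, _out(config, "cohort.csv"))
    cohort_truth.to_csv(_out(config, "cohort_truth.tsv"), sep="\t", index=False)

    # gene sets: the four planted categories plus random null sets
    rng = np.random.default_rng(config.stage_seed("gene_sets"))
    sets: dict[str, frozenset[str]] = {}
    for cat in synthdata.CATEGORY_NAMES:
        members = truth.loc[truth["category"] == cat, "gene_id"]
        if len(members):
            sets[f"planted_{cat}"] = frozenset(members)
    all_genes = np.array(truth["gene_id"])
    for i in range(4):
        sets[f"random_set_{i}"] = frozenset(
            rng.choice(all_genes, size=50, replace=False)
        )
    write_gene_sets(GeneSetCollection(sets), _out(config, "gene_sets.gmt"))
    return {
        "genes": len(truth),
        "samples": len(m.sample_ids),
        "track_genes": len(track_truth),
        "patients": len(records),
        "gene_sets": len(sets),
    }


def _inputs(config: RunConfig, name: str) -> Path:
    if config.simulate:
        return _out(config, name)
    mapping = {
        "counts.tsv": config.counts_path,
        "samples.csv": config.samples_path,
        "transcripts.bed": config.transcripts_path,
        "gene_sets.gmt": config.gene_sets_path,
        "cohort.csv": config.clinical_path,
    }
    path = mapping.get(name)
    if path is None:
        raise FileNotFoundError(f"missing input: {name} (set the config path)")
    return Path(path)


def stage_de(config: RunConfig) -> dict:
    m = read_counts(_inputs(config, "counts.tsv"), _inputs(config, "samples.csv"))
    table = diffexpr.contrast_table(m)
    table.to_csv(_out(config, "contrasts.tsv"), sep="\t", index_label="gene_id")
    n_sig = {}
    for contrast in diffexpr.CONTRASTS:
        sig = diffexpr.significant_genes(table, contrast, config.alpha)
        n_sig[contrast] = len(sig)
        ranked = table.loc[
            table[f"p_{contrast}"] < config.alpha, f"log2fc_{contrast}"
        ].sort_values(ascending=False)
        write_rnk(list(ranked.index), list(ranked), _out(config, f"ranked_{contrast}.rnk"))
    return {"genes": len(table), "significant": n_sig}


def stage_classify(config: RunConfig) -> dict:
    table = pd.read_csv(_out(config, "contrasts.tsv"), sep="\t", index_col="gene_id")
    calls = coregulation.classify_all(table, alpha=config.alpha)
    calls.to_csv(_out(config, "category_calls.tsv"), sep="\t")
    sig_sets = {
        c: diffexpr.significant_genes(table, c, config.alpha)
        for c in diffexpr.CONTRASTS
    }
    overlaps = coregulation.overlap_counts(sig_sets)
    with open(_out(config, "overlap_counts.json"), "w") as fh:
        json.dump(overlaps, fh, indent=2, sort_keys=True)
    by_cat = calls["category"].value_counts().to_dict()
    return {"calls": len(calls), "by_category": {k: int(v) for k, v in by_cat.items()}}


def stage_enrich(config: RunConfig) -> dict:
    table = pd.read_csv(_out(config, "contrasts.tsv"), sep="\t", index_col="gene_id")
    gsc = read_gene_sets(_inputs(config, "gene_sets.gmt"))
    ranked = enrichment.make_ranked_list(table, "siNELFA", alpha=config.alpha)
    gsea = enrichment.gsea_collection(
        ranked,
        dict(gsc.sets),
        weight=config.gsea_weight,
        n_perm=config.gsea_n_perm,
        seed=config.stage_seed("gsea"),
        min_size=config.gsea_min_size,
        max_size=config.gsea_max_size,
    )
    gsea.to_csv(_out(config, "gsea_results.tsv"), sep="\t", index=False)

    universe = set(table.index)
    deg = diffexpr.significant_genes(table, "siNELFA", config.alpha)
    rows = []
    for name, members in gsc.sets.items():
        r = enrichment.fisher_overlap(deg, members, universe, term_name=name)
        rows.append(
            {"term": r.term, "overlap": r.overlap, "p": r.p, "odds_ratio": r.odds_ratio}
        )
    fisher = pd.DataFrame(rows)
    fisher.to_csv(_out(config, "fisher_overlap.tsv"), sep="\t", index=False)
    return {"gsea_sets": len(gsea), "fisher_terms": len(fisher)}


def stage_pausing(config: RunConfig) -> dict:
    transcripts = read_transcripts(_inputs(config, "transcripts.bed"))
    tdir = (
        Path(config.outdir) / "tracks"
        if config.simulate
        else Path(config.tracks_dir or "")
    )
    tracks = {name: read_track(tdir / f"{name}.bedGraph") for name in TRACK_NAMES}
    quant = pausing.quantify(
        transcripts,
        chip_baseline=tracks["chip_baseline"],
        chip_perturbed=tracks["chip_perturbed"],
        input_track=tracks["input"],
        nascent_plus_baseline=tracks["nascent_plus_baseline"],
        nascent_minus_baseline=tracks["nascent_minus_baseline"],
        nascent_plus_perturbed=tracks["nascent_plus_perturbed"],
        nascent_minus_perturbed=tracks["nascent_minus_perturbed"],
        eps=config.pausing_eps,
    )
    calls = pausing.call_pausing(
        quant,
        retention_threshold=config.retention_threshold,
        loss_fraction=config.pausing_loss_fraction,
    )
    calls.to_csv(_out(config, "pausing_calls.tsv"), sep="\t")
    by_call = calls["call"].value_counts().to_dict()
    return {"genes": len(calls), "by_call": {k: int(v) for k, v in by_call.items()}}


def stage_clinical(config: RunConfig) -> dict:
    records = read_clinical(_inputs(config, "cohort.csv"))
    scores = clin.marker_scores(records)
    scores.to_csv(_out(config, "composite_scores.tsv"), sep="\t")
    dfs_events = [r.dfs_event for r in records]
    cutoffs = {}
    roc = {}
    for marker, col in (("YAP", "yap_score"), ("NELFA", "nelfa_score")):
        cut, sens, spec = clin.roc_cutoff(scores[col], dfs_events)
        cutoffs[marker] = cut
        roc[marker] = {"cutoff": cut, "sensitivity": sens, "specificity": spec}

    out: dict = {"patients": len(records), "roc": roc}
    for endpoint in ("OS", "DFS"):
        grouping = clin.stratify(records, mode="joint", cutoffs=cutoffs, endpoint=endpoint)
        km_tables = []
        for group in grouping.groups():
            km = clin.km_curve(grouping, group)
            km.insert(0, "group", group)
            km_tables.append(km)
        pd.concat(km_tables).to_csv(
            _out(config, f"km_{endpoint.lower()}.tsv"), sep="\t", index=False
        )
        try:
            chi2_stat, df, p = clin.logrank_test(grouping)
            out[f"logrank_{endpoint.lower()}"] = {"chi2": chi2_stat, "df": df, "p": p}
        except ValueError as err:
            out[f"logrank_{endpoint.lower()}"] = {"error": str(err)}

    grouping = clin.stratify(records, mode="joint", cutoffs=cutoffs, endpoint="OS")
    tab = pd.crosstab(
        [r.subtype for r in records], grouping.table.set_index("patient_id")["group"]
    )
    res = clin.chi2_contingency(tab.to_numpy())
    out["subtype_by_group_chi2"] = {"chi2": res.statistic, "df": res.df, "p": res.p}
    with open(_out(config, "clinical_summary.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "classify": stage_classify,
    "enrich": stage_enrich,
    "pausing": stage_pausing,
    "clinical": stage_clinical,
}

#: Primary output per stage, used for resume detection.
_STAGE_SENTINELS = {
    "simulate": "counts.tsv",
    "de": "contrasts.tsv",
    "classify": "category_calls.tsv",
    "enrich": "gsea_results.tsv",
    "pausing": "pausing_calls.tsv",
    "clinical": "clinical_summary.json",
}


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    ``resume=True`` skips stages whose primary output already exists.  A stage
    failure aborts the run with the failing stage named.
    """
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "version": __version__,
        "stages": {},
    }
    for stage in chosen:
        sentinel = _out(config, _STAGE_SENTINELS[stage])
        if resume and sentinel.exists():
            log.info("stage %s: resumed (output exists)", stage)
            manifest["stages"][stage] = {"resumed": True}
            continue
        log.info("stage %s: running", stage)
        try:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](config)
        except Exception as err:
            manifest["stages"][stage] = {"failed": str(err)}
            with open(_out(config, "manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    with open(_out(config, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
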