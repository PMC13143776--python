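"""Readers and writers for every external format the pipeline touches.

All genomic intervals are 0-based, half-open internally; GTF records (1-based,
closed) are converted on read.  Formats handled: TSV count matrix + CSV sample
sheet, GTF2.2 / BED6 transcript annotation, bedGraph (BigWig optionally, behind
the same contract), GMT gene sets, RNK ranked lists, and the clinical CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four knockdown conditions of the expression experiment.
CONDITIONS = ("siControl", "siNELFA", "siYAP", "siNELFA_siYAP")

#: Breast-cancer molecular subtypes used by the clinical module.
SUBTYPES = ("ER+", "HER2+", "TNBC")


class DataValidationError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with a condition/replicate design.

    ``counts`` is an integer DataFrame indexed by gene id with one column per
    sample; ``samples`` is indexed by sample id with columns ``condition`` and
    ``replicate``, in the same column order as ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataValidationError(f"duplicate gene id: {dup}")
        if list(self.counts.columns) != list(self.samples.index):
            raise DataValidationError("sample order mismatch between counts and sheet")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise DataValidationError("non-integer count")
        if (vals < 0).any():
            raise DataValidationError("negative count")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise DataValidationError(f"unknown condition label: {sorted(bad)}")
        if (self.samples["replicate"].astype(int) < 1).any():
            raise DataValidationError("replicate indices must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_samples(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise DataValidationError(f"unknown condition label: {condition}")
        return list(self.samples.index[self.samples["condition"] == condition])


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix plus its CSV sample sheet into a CountMatrix.

    The TSV has a header of sample ids and gene ids in the first column; the
    sheet has columns ``sample_id``, ``condition``, ``replicate``.  Samples are
    reordered to follow the sheet.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    sheet = pd.read_csv(samples_path)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(sheet.columns):
        raise DataValidationError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in sheet.index if s not in counts.columns]
    if missing:
        raise DataValidationError(f"sample missing from count matrix: {missing}")
    counts = counts[list(sheet.index)]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        flo = counts.astype(float).to_numpy()
        if not np.allclose(flo, np.round(flo)):
            raise DataValidationError("non-integer count")
        counts = counts.astype(np.int64)
    return CountMatrix(counts=counts, samples=sheet[["condition", "replicate"]])


def write_counts(m: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    m.samples.to_csv(samples_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataValidationError(f"unknown strand: {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise DataValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.transcript_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_line(line: str) -> TranscriptModel | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9:
        raise DataValidationError(f"malformed GTF line: {line[:80]!r}")
    chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
    if feature != "transcript":
        return None
    attr = dict(_GTF_ATTR.findall(attrs))
    if "gene_id" not in attr or "transcript_id" not in attr:
        raise DataValidationError(f"malformed attribute string: {attrs[:80]!r}")
    # GTF is 1-based closed; internal convention is 0-based half-open.
    s, e = int(start) - 1, int(end)
    return TranscriptModel(chrom, s, e, strand, attr["gene_id"], attr["transcript_id"])


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript records from GTF (``transcript`` features) or BED6.

    BED6 names carry ``gene_id|transcript_id``.  Dispatch is by extension:
    ``.bed`` is BED6, anything else is treated as GTF.
    """
    path = Path(path)
    out: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if path.suffix == ".bed":
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise DataValidationError(f"BED6 line with {len(f)} fields")
                if "|" not in f[3]:
                    raise DataValidationError(f"BED name must be gene_id|transcript_id: {f[3]!r}")
                gid, tid = f[3].split("|", 1)
                rec = TranscriptModel(f[0], int(f[1]), int(f[2]), f[5], gid, tid)
            else:
                maybe = _parse_gtf_line(line)
                if maybe is None:
                    continue
                rec = maybe
            if rec.transcript_id in seen:
                raise DataValidationError(f"duplicate transcript_id: {rec.transcript_id}")
            seen.add(rec.transcript_id)
            out.append(rec)
    return out


def write_transcripts_bed(ts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_id}|{t.transcript_id}\t0\t{t.strand}\n"
            )


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


class SignalTrack:
    """Piecewise-constant coverage, per chromosome.

    Bases not covered by any interval have value 0 and are included in window
    means (coverage-track semantics).  Intervals within a chromosome must be
    non-overlapping; unsorted input is sorted internally.
    """

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        strand: str | None = None,
    ) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.strand = strand
        if intervals:
            for chrom, (s, e, v) in intervals.items():
                self._add_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    def _add_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray) -> None:
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order].astype(float)
        if not np.all(np.isfinite(values)):
            raise DataValidationError(f"non-finite value on {chrom}")
        if np.any(ends <= starts):
            raise DataValidationError(f"empty interval on {chrom}")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise DataValidationError(f"overlapping intervals on {chrom}")
        self._chroms[chrom] = (starts.astype(np.int64), ends.astype(np.int64), values)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty query window")
        return self.sum(chrom, start, end) / (end - start)

    def sum(self, chrom: str, start: int, end: int) -> float:
        """Base-pair-weighted sum of signal over [start, end)."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))


def read_track(path: str | Path, strand: str | None = None) -> SignalTrack:
    """Read a bedGraph (4-column) or BigWig file into a SignalTrack.

    BigWig support requires the optional pyBigWig dependency; bedGraph is the
    required text surface.
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_bigwig(path, strand)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise DataValidationError(f"bedGraph line with {len(f)} fields")
            try:
                s, e, v = int(f[1]), int(f[2]), float(f[3])
            except ValueError as err:
                raise DataValidationError(f"non-numeric bedGraph field: {line[:80]!r}") from err
            per_chrom.setdefault(f[0], []).append((s, e, v))
    ivs = {
        c: (
            np.array([x[0] for x in rows]),
            np.array([x[1] for x in rows]),
            np.array([x[2] for x in rows]),
        )
        for c, rows in per_chrom.items()
    }
    return SignalTrack(ivs, strand=strand)


def _read_bigwig(path: Path, strand: str | None) -> SignalTrack:
    try:
        import pyBigWig  # type: ignore
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("BigWig support requires the optional pyBigWig extra") from err
    bw = pyBigWig.open(str(path))
    ivs = {}
    for chrom in bw.chroms():
        rows = bw.intervals(chrom) or []
        ivs[chrom] = (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
    bw.close()
    return SignalTrack(ivs, strand=strand)


def write_track(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack as bedGraph, omitting zero-value runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and ranked lists (RNK)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataValidationError(f"empty gene set: {name}")

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping sets that empty out."""
        uni = frozenset(universe)
        kept = {n: s & uni for n, s in self.sets.items() if s & uni}
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise DataValidationError(f"gene set with 0 members: {f[0]!r}")
            name = f[0]
            if name in sets:
                raise DataValidationError(f"duplicate set name: {name}")
            members = frozenset(g for g in f[2:] if g)
            if not members:
                raise DataValidationError(f"gene set with 0 members: {name!r}")
            sets[name] = members
            desc[name] = f[1]
    return GeneSetCollection(sets, desc)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_rnk(genes: Sequence[str], scores: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"gene": genes, "score": scores}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_rnk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["gene"].duplicated().any():
        raise DataValidationError("duplicate gene in RNK file")
    return df


def collapse_gene_scores(
    genes: Sequence[str], scores: Sequence[float], policy: str = "max_abs"
) -> tuple[list[str], list[float]]:
    """Resolve duplicate gene symbols (e.g. after Ensembl->HGNC conversion).

    ``max_abs`` (default) keeps the score of largest magnitude per symbol;
    ``drop`` removes every symbol that occurs more than once.
    """
    df = pd.DataFrame({"gene": genes, "score": scores})
    if policy == "max_abs":
        keep = (
            df.reindex(df["score"].abs().sort_values(ascending=False, kind="stable").index)
            .drop_duplicates("gene")
            .sort_index()
            .reset_index(drop=True)
        )
    elif policy == "drop":
        counts = df["gene"].value_counts()
        keep = df[df["gene"].map(counts) == 1].reset_index(drop=True)
    else:
        raise ValueError(f"unknown duplicate policy: {policy}")
    return list(keep["gene"]), list(keep["score"])


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------


@dataclass
class ClinicalRecord:
    """Per-patient subtype, two-marker IHC scores and survival endpoints."""

    patient_id: str
    subtype: str
    yap_percent: float
    nelfa_percent: float
    yap_intensity: int
    nelfa_intensity: int
    os_months: float
    dfs_months: float
    os_event: int
    dfs_event: int
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise DataValidationError(f"unknown subtype: {self.subtype!r}")
        for name in ("yap_percent", "nelfa_percent"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise DataValidationError(f"{name} outside [0,100]: {v}")
        for name in ("yap_intensity", "nelfa_intensity"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise DataValidationError(f"{name} outside {{0..3}}: {v}")
        for name in ("os_months", "dfs_months"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"negative time: {name}")
        for name in ("os_event", "dfs_event"):
            if getattr(self, name) not in (0, 1):
                raise DataValidationError(f"non-binary event flag: {name}")


_CLINICAL_REQUIRED = [
    "patient_id", "subtype", "yap_percent", "nelfa_percent",
    "yap_intensity", "nelfa_intensity", "os_months", "dfs_months",
    "os_event", "dfs_event",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical CSV; optional covariate columns are carried along."""
    df = pd.read_csv(path)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise DataValidationError(f"clinical table missing columns: {missing}")
    extra = [c for c in df.columns if c not in _CLINICAL_REQUIRED]
    records = []
    for _, row in df.iterrows():
        for ev in ("os_event", "dfs_event"):
            if pd.isna(row[ev]):
                raise DataValidationError(f"event required (row {row['patient_id']})")
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                subtype=str(row["subtype"]),
                yap_percent=float(row["yap_percent"]),
                nelfa_percent=float(row["nelfa_percent"]),
                yap_intensity=int(row["yap_intensity"]),
                nelfa_intensity=int(row["nelfa_intensity"]),
                os_months=float(row["os_months"]),
                dfs_months=float(row["dfs_months"]),
                os_event=int(row["os_event"]),
                dfs_event=int(row["dfs_event"]),
                covariates={c: row[c] for c in extra if not pd.isna(row[c])},
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    extra = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _CLINICAL_REQUIRED}
        row.update({k: r.covariates.get(k, "") for k in extra})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
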