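"""Pre-ranked gene-set enrichment and Fisher-exact overlap enrichment.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running-sum statistic: walking down the ranked list, genes in the set add
|score|^weight normalized by the total hit weight, genes outside subtract
1/(N - n_hits); ES is the signed maximum deviation from zero.  Significance
comes from a gene-sampling null (random same-size sets drawn from the ranked
universe): NES divides ES by the mean |null ES| of matching sign, and the
nominal p-value is the +1-smoothed same-sign tail fraction.

Transcription-factor-target overlap enrichment is the one-sided Fisher exact
test on the 2x2 membership table, with an odds ratio using the Haldane +0.5
correction when any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RankedList:
    """Gene ids with scores, sorted descending (ties by gene id)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    size: int


@dataclass
class OverlapResult:
    term: str
    overlap: int
    p: float
    odds_ratio: float


def make_ranked_list(table: pd.DataFrame, contrast: str, alpha: float = 0.05) -> RankedList:
    """Rank significant genes of a contrast by log2 fold change, descending.

    Only genes with nominal p < alpha enter the ranking; ties in fold change
    are broken by gene id (lexicographic).
    """
    pcol, fcol = f"p_{contrast}", f"log2fc_{contrast}"
    if pcol not in table.columns or fcol not in table.columns:
        raise KeyError(f"unknown contrast: {contrast}")
    sub = table.loc[table[pcol] < alpha, [fcol]].copy()
    if len(sub) < 10:
        raise ValueError(f"ranking too short: {len(sub)} genes survive p < {alpha}")
    sub["gene"] = sub.index
    sub = sub.sort_values([fcol, "gene"], ascending=[False, True], kind="stable")
    return RankedList(list(sub["gene"]), sub[fcol].to_numpy())


def _es_from_hits(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("empty intersection between set and ranking")
    if n_hits == n:
        return 1.0
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal steps
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_es(ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Enrichment score of one gene set against a ranked list."""
    members = set(gene_set)
    hit_mask = np.array([g in members for g in ranked.genes])
    return _es_from_hits(ranked.scores, hit_mask, weight)


def gsea_nes_p(
    ranked: RankedList,
    gene_set: Iterable[str],
    name: str = "",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """ES plus NES and nominal p from a gene-sampling null.

    The null draws ``n_perm`` random gene sets of the observed intersection
    size from the ranked universe.  NES = ES / mean(|null ES| of the same
    sign); p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign
    null).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    members = set(gene_set)
    hit_mask = np.array([g in members for g in ranked.genes])
    size = int(hit_mask.sum())
    es = _es_from_hits(ranked.scores, hit_mask, weight)

    rng = np.random.default_rng(seed)
    n = len(ranked.genes)
    null = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        mask[:] = False
        mask[rng.choice(n, size=size, replace=False)] = True
        null[i] = _es_from_hits(ranked.scores, mask, weight)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    n_same = len(same_sign)
    denom = np.mean(np.abs(same_sign)) if n_same else 1.0
    nes = es / denom if denom > 0 else 0.0
    p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + n_same)
    return GseaResult(name=name, es=es, nes=nes, p=p, size=size)


def gsea_collection(
    ranked: RankedList,
    sets: dict[str, frozenset[str] | set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Run gsea_nes_p over a collection, filtering by post-intersection size."""
    universe = set(ranked.genes)
    rows = []
    rng = np.random.default_rng(seed)
    for name, members in sets.items():
        size = len(set(members) & universe)
        if not min_size <= size <= max_size:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        r = gsea_nes_p(ranked, members, name=name, weight=weight, n_perm=n_perm, seed=sub_seed)
        rows.append({"name": name, "size": r.size, "es": r.es, "nes": r.nes, "p": r.p})
    return pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p"])


def fisher_overlap(
    deg: Iterable[str], term: Iterable[str], universe: Iterable[str], term_name: str = ""
) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test for a DEG/term overlap.

    The 2x2 table partitions the universe by DEG membership and term
    membership.  The odds ratio is ad/bc with the Haldane +0.5 correction
    applied to every cell when any cell is zero.
    """
    uni = set(universe)
    deg_s = set(deg) & uni
    term_s = set(term) & uni
    if not uni or not deg_s:
        raise ValueError("empty universe or DEG list")
    a = len(deg_s & term_s)
    b = len(deg_s) - a
    c = len(term_s) - a
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return OverlapResult(term=term_name, overlap=a, p=float(p), odds_ratio=float(odds))
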