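"""The four-category NELFA x YAP co-regulation classifier and set overlaps.

A gene's three knockdown log2 fold changes (siNELFA, siYAP, and the double
knockdown, each versus control) place it in at most one of four mutually
exclusive categories:

1. ``NELFA_suppressed_YAP_activated`` — up on NELFA loss, down on YAP loss,
   near-baseline in the double knockdown;
2. ``NELFA_activated_YAP_suppressed`` — the mirror pattern;
3. ``co_suppressed`` — up in both single knockdowns and at least as far up in
   the double (both factors repress the gene);
4. ``co_activated`` — down in both singles and at least as far down in the
   double (both factors are required for expression).

Thresholds use the non-strict printed boundaries (>= +1 / <= -1 on the single
knockdowns) and a strict interior (-1, +1) for the double knockdown in
categories 1-2.  For categories 3-4 the double-knockdown condition is the
"most extreme in the double" comparison against the single-knockdown fold
changes.
"""

from __future__ import annotations

import itertools
import math

import pandas as pd

from .diffexpr import CONTRASTS
from .synthdata import CATEGORY_NAMES


def classify_gene(fc_n: float, fc_y: float, fc_d: float) -> str:
    """Classify one gene from its (siNELFA, siYAP, double) log2 fold changes.

    Returns one of the four category names or ``"none"``.
    """
    for v in (fc_n, fc_y, fc_d):
        if not math.isfinite(v):
            raise ValueError("non-finite log2 fold change")
    if fc_n >= 1 and fc_y <= -1 and -1 < fc_d < 1:
        return CATEGORY_NAMES[0]
    if fc_n <= -1 and fc_y >= 1 and -1 < fc_d < 1:
        return CATEGORY_NAMES[1]
    if fc_n >= 1 and fc_y >= 1 and fc_d >= max(fc_n, fc_y):
        return CATEGORY_NAMES[2]
    if fc_n <= -1 and fc_y <= -1 and fc_d <= min(fc_n, fc_y):
        return CATEGORY_NAMES[3]
    return "none"


def classify_all(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the classifier to every gene passing the significance gate.

    The gate requires nominal p < alpha in *both* single-knockdown contrasts
    (the weakest gate under which all four categories are defined); genes
    failing it are called ``"none"``.  Input is the three-contrast table from
    :func:`nelfyap.diffexpr.contrast_table`.
    """
    needed = [f"{stat}_{c}" for c in CONTRASTS for stat in ("log2fc", "p")]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise KeyError(f"missing contrast columns: {missing}")
    fc_n = table["log2fc_siNELFA"]
    fc_y = table["log2fc_siYAP"]
    fc_d = table["log2fc_siNELFA_siYAP"]
    gate = (table["p_siNELFA"] < alpha) & (table["p_siYAP"] < alpha)
    cats = [
        classify_gene(n, y, d) if g else "none"
        for n, y, d, g in zip(fc_n, fc_y, fc_d, gate)
    ]
    return pd.DataFrame(
        {
            "gene_id": table.index,
            "category": cats,
            "log2fc_siNELFA": fc_n.to_numpy(),
            "log2fc_siYAP": fc_y.to_numpy(),
            "log2fc_siNELFA_siYAP": fc_d.to_numpy(),
            "passed_gate": gate.to_numpy(),
        }
    ).set_index("gene_id")


def overlap_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    """Exact cardinality of every region of the Venn partition of 2-4 sets.

    Keys are membership signatures over the set names in insertion order
    ("110" = in the first two sets only); per-set totals are included under
    ``total:<name>``.
    """
    names = list(sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set name")
    if not 2 <= len(names) <= 4:
        raise ValueError("overlap_counts takes 2-4 named sets")
    universe = set().union(*sets.values())
    out: dict[str, int] = {}
    for mask in itertools.product((1, 0), repeat=len(names)):
        if not any(mask):
            continue
        region = set(universe)
        for name, bit in zip(names, mask):
            region = region & sets[name] if bit else region - sets[name]
        out["".join(map(str, mask))] = len(region)
    for name in names:
        out[f"total:{name}"] = len(sets[name])
    return out
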