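"""Small published reference tables used as worked examples and checks.

Two kinds of inputs are bundled as plain Python literals:

* clinicopathological contingency tables from a 75-patient invasive ductal
  carcinoma cohort, cross-tabulating clinical features against molecular
  subtype or dichotomized YAP/NELFA IHC expression — inputs for the
  uncorrected Pearson chi-square test;
* per-gene promoter NELF-C occupancy (log2 ChIP/input) and gene-body nascent
  output, before and after acute NELF-C degradation, for seven representative
  YAP-target genes — inputs for the coordinated-loss caller.
"""

from __future__ import annotations

import pandas as pd

#: Contingency tables (rows x columns of patient counts).  Keys describe the
#: cross-tabulation; values are (table, row_labels, col_labels).
CONTINGENCY_TABLES: dict[str, tuple[list[list[int]], list[str], list[str]]] = {
    # tumour grade (low I/II vs high III) across molecular subtypes
    "grade_by_subtype": (
        [[24, 8, 6], [7, 10, 17]],
        ["low_grade", "high_grade"],
        ["ER+", "HER2+", "TNBC"],
    ),
    # menopausal status across NELFA-high/low IHC groups
    "menopause_by_nelfa": (
        [[8, 7], [23, 26]],
        ["pre", "post"],
        ["high_NELFA", "low_NELFA"],
    ),
    # tumour grade across YAP-high/low IHC groups
    "grade_by_yap": (
        [[24, 13], [14, 20]],
        ["low_grade", "high_grade"],
        ["high_YAP", "low_YAP"],
    ),
    # clinical node status across YAP-high/low IHC groups
    "node_by_yap": (
        [[8, 14], [29, 20]],
        ["negative", "positive"],
        ["high_YAP", "low_YAP"],
    ),
    # molecular subtype across YAP-high/low IHC groups
    "subtype_by_yap": (
        [[18, 13], [11, 9], [11, 12]],
        ["ER+", "HER2+", "TNBC"],
        ["high_YAP", "low_YAP"],
    ),
    # molecular subtype across the four joint YAP x NELFA IHC groups
    "subtype_by_joint": (
        [[9, 9, 7, 6], [8, 3, 3, 6], [5, 6, 5, 8]],
        ["ER+", "HER2+", "TNBC"],
        [
            "HighYAP_HighNELFA",
            "HighYAP_LowNELFA",
            "LowYAP_HighNELFA",
            "LowYAP_LowNELFA",
        ],
    ),
}


def nelf_degron_occupancy() -> pd.DataFrame:
    """Promoter occupancy and gene-body output around acute NELF-C loss.

    Columns match the quantification contract of
    :func:`nelfyap.pausing.call_pausing`: baseline/perturbed promoter
    log2(ChIP/input) and baseline/perturbed gene-body nascent output for
    seven YAP-target genes with reported coordinated occupancy loss.
    """
    rows = [
        # gene, category, occ baseline, occ degraded, output baseline, output degraded
        ("FAM129C", "co_suppressed", 2.81, 0.19, 2.41, 3.05),
        ("SLITRK6", "YAP_signature", 3.20, -0.16, 0.52, 0.96),
        ("APOBR", "co_suppressed", 2.82, 0.99, 0.48, 0.70),
        ("C8orf74", "co_suppressed", 2.92, -0.07, 0.82, 1.01),
        ("FOLR3", "NELFA_suppressed_YAP_activated", 0.57, 0.03, 0.93, 1.07),
        ("KCNC3", "co_suppressed", 2.31, 0.09, 0.91, 0.93),
        ("HEG1", "YAP_signature", 2.66, -0.004, 0.76, 0.77),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "annotation",
            "promoter_enrichment_baseline",
            "promoter_enrichment_perturbed",
            "genebody_output_baseline",
            "genebody_output_perturbed",
        ],
    ).set_index("gene_id")
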