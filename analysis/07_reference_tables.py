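#!/usr/bin/env python
"""Recompute the published reference statistics bundled with the package.

Re-derives every cohort chi-square p-value from the published patient
counts with the uncorrected Pearson test, and runs the coordinated-loss
caller on the published NELF-C degron promoter/output quantifications.
"""

from nelfyap import clinical as cl
from nelfyap import datasets, pausing


def main() -> None:
    print("cohort contingency tables (uncorrected Pearson chi-square):")
    for key, (table, _, _) in datasets.CONTINGENCY_TABLES.items():
        res = cl.chi2_contingency(table)
        print(f"  {key:<22} chi2={res.statistic:7.4f} df={res.df} p={res.p:.4f}")

    df = datasets.nelf_degron_occupancy()
    calls = pausing.call_pausing(df)
    print("NELF-C degron occupancy calls:")
    for gene, row in calls.iterrows():
        print(
            f"  {gene:<8} occupancy {row['promoter_enrichment_baseline']:+.2f} -> "
            f"{row['promoter_enrichment_perturbed']:+.2f}, output "
            f"{row['genebody_output_baseline']:.2f} -> "
            f"{row['genebody_output_perturbed']:.2f}: {row['call']}"
        )


if __name__ == "__main__":
    main()
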