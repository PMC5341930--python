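#!/usr/bin/env python
"""Cohort expression analysis: miR-30 levels across disease groups and their
correlation with PSA mRNA as an AR-activity surrogate.

RNU6B-normalizes the ddPCR miR-30 quantifications, computes PSA relative
quantity vs beta-actin, tests each group against normal prostate, correlates
miR-30 levels with PSA across the CRPC samples (Pearson and Spearman), and
applies the BH-FDR + fold-change differential-expression filter.
"""

import argparse
from pathlib import Path

import pandas as pd

from arscreen import expression_stats as es
from arscreen import io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    table, _ = io.read_cohort_table(args.data / "cohort.tsv")
    groups = es.sample_groups(table)
    levels, excluded = es.normalize_ddpcr(table)
    psa = es.relative_qpcr(table)

    comp = es.group_compare(levels, groups)
    io.write_tsv(comp, args.out / "group_tests.tsv")
    for _, row in comp.iterrows():
        mark = "*" if row["significant"] else " "
        print(
            f"{row['analyte']:11s} {row['group']:8s} ratio vs normal = "
            f"{row['ratio_vs_reference']:.2f}  p = {row['p_value']:.3g} {mark}"
        )

    crpc = groups[groups == "CRPC"].index
    rows = []
    for analyte in levels.columns:
        for method in ("pearson", "spearman"):
            r, p, n = es.correlate(
                levels.loc[crpc, analyte], psa.loc[psa.index.intersection(crpc)], method
            )
            rows.append({"analyte": analyte, "method": method, "r": r, "p": p, "n": n})
    corr = pd.DataFrame(rows)
    io.write_tsv(corr, args.out / "psa_correlations.tsv")
    d30 = corr[(corr["analyte"] == "miR-30d-5p") & (corr["method"] == "pearson")].iloc[0]
    print(
        f"\nmiR-30d-5p vs PSA mRNA in CRPC: Pearson r = {d30['r']:.3f} "
        f"(p = {d30['p']:.3g}, n = {int(d30['n'])})"
    )

    two = groups[groups.isin(["normal", "CRPC"])]
    expr = levels.dropna().T
    expr = expr.loc[:, expr.columns.intersection(two.index)]
    de = es.de_filter(expr, two, reference_group="normal")
    io.write_tsv(de.reset_index().rename(columns={"index": "analyte"}), args.out / "de_filter.tsv")
    print(
        f"DE filter (FDR < 0.05, |FC| > 1.2), CRPC vs normal: "
        f"{int(de['passes'].sum())} of {len(de)} miR-30 members pass"
    )


if __name__ == "__main__":
    main()
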