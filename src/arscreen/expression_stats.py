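"""Cohort expression statistics: ddPCR/qPCR normalization, group tests,
correlation, and the FDR + fold-change differential-expression filter.

The cohort table is long-format with one row per (sample, analyte,
measure_type): ddPCR absolute copy counts for miRNAs and the RNU6B reference,
and qPCR Ct values for PSA and the beta-actin reference.  miRNA levels are
reported relative to RNU6B copies in the same sample; PSA is reported as
2^-dCt relative to beta-actin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import COHORT_COLUMNS  # shared long-format schema

GROUPS = ("normal", "primary", "CRPC")


def _pivot(table: pd.DataFrame, measure_type: str) -> pd.DataFrame:
    sub = table[table["measure_type"] == measure_type]
    return sub.pivot_table(
        index="sample_id", columns="analyte", values="value", aggfunc="first"
    )


def sample_groups(table: pd.DataFrame) -> pd.Series:
    return table.drop_duplicates("sample_id").set_index("sample_id")["group"]


def normalize_ddpcr(
    table: pd.DataFrame, reference: str = "RNU6B"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample miRNA levels relative to the reference gene's copy count.

    Returns ``(levels, excluded)``: ``levels`` is samples x analytes (the
    reference column dropped); samples whose reference copies are <= 0 are set
    to NaN for every analyte and listed in ``excluded``.
    """
    copies = _pivot(table, "ddpcr_copies")
    if reference not in copies.columns:
        raise ValueError(f"reference analyte {reference!r} absent from ddPCR data")
    ref = copies[reference]
    bad = ref <= 0
    levels = copies.drop(columns=[reference]).div(ref.where(~bad), axis=0)
    return levels, sorted(ref.index[bad])


def relative_qpcr(
    table: pd.DataFrame, target: str = "PSA", reference: str = "ACTB"
) -> pd.Series:
    """Relative quantity 2^-(Ct_target - Ct_reference) per sample."""
    ct = _pivot(table, "qpcr_ct")
    for analyte in (target, reference):
        if analyte not in ct.columns:
            raise ValueError(f"analyte {analyte!r} absent from qPCR data")
    rq = np.power(2.0, -(ct[target] - ct[reference]))
    rq.name = target
    return rq


def group_compare(
    levels: pd.Series | pd.DataFrame,
    groups: pd.Series,
    reference_group: str = "normal",
) -> pd.DataFrame:
    """Welch t-tests of each group vs the reference group, on log2 levels.

    Returns one row per (analyte, group): ratio of geometric means vs the
    reference group, two-sided p value, and significance at 0.05.  NaN levels
    (e.g. reference-gene failures) are excluded pairwise.  Groups with fewer
    than 2 finite observations for an analyte raise.
    """
    if isinstance(levels, pd.Series):
        levels = levels.to_frame()
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} not present")
    rows = []
    for analyte in levels.columns:
        logv = np.log2(levels[analyte].astype(float))
        by = {
            g: logv[groups.reindex(logv.index) == g].dropna().to_numpy()
            for g in pd.unique(groups)
        }
        ref = by[reference_group]
        if len(ref) < 2:
            raise ValueError(f"{analyte}: reference group has < 2 observations")
        for g, vals in by.items():
            if g == reference_group:
                continue
            if len(vals) < 2:
                raise ValueError(f"{analyte}: group {g!r} has < 2 observations")
            t, p = stats.ttest_ind(vals, ref, equal_var=False)
            rows.append(
                {
                    "analyte": analyte,
                    "group": g,
                    "ratio_vs_reference": float(2.0 ** (vals.mean() - ref.mean())),
                    "p_value": float(p) if np.isfinite(p) else 1.0,
                    "significant": bool(np.isfinite(p) and p < 0.05),
                }
            )
    return pd.DataFrame(rows)


def correlate(
    x: pd.Series, y: pd.Series, method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlation of paired complete observations; (r, two-sided p, n).

    Pearson p uses the t approximation; Spearman p is exact for small n per
    scipy's implementation.  Requires >= 3 complete pairs.
    """
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"correlate requires >= 3 complete pairs, got {n}")
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), n


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def de_filter(
    expr: pd.DataFrame,
    groups: pd.Series,
    reference_group: str | None = None,
    fdr_alpha: float = 0.05,
    min_fc: float = 1.2,
) -> pd.DataFrame:
    """Differential-expression filter: BH-FDR < alpha and linear |FC| > min_fc.

    ``expr`` is features x samples on a linear scale; tests are two-sided
    Welch t-tests on log2 values between the two groups present.  Returns per
    feature: log2_fc (other vs reference), p, q (BH), passes.
    """
    labels = sorted(pd.unique(groups.reindex(expr.columns).dropna()))
    if len(labels) != 2:
        raise ValueError(f"de_filter needs exactly 2 groups, got {labels}")
    if reference_group is None:
        reference_group = labels[0]
    other = [g for g in labels if g != reference_group][0]
    g = groups.reindex(expr.columns)
    a = np.log2(expr.loc[:, (g == other).to_numpy()].to_numpy(float))
    b = np.log2(expr.loc[:, (g == reference_group).to_numpy()].to_numpy(float))
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": p,
            "q_value": q,
            "passes": (q < fdr_alpha) & (2.0 ** np.abs(lfc) > min_fc),
        },
        index=expr.index,
    )
    out.attrs["comparison"] = f"{other}_vs_{reference_group}"
    return out
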