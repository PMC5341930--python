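"""Plate-based assay normalization and verification statistics.

Reporter wells carry paired firefly (AR-responsive PSE-PBN promoter) and
Renilla (constitutive, transfection control) luminescence; the per-well
firefly/Renilla ratio is averaged per mimic and expressed as fold change vs
the control mimic(s).  Viability wells carry a single secreted-MLuc reading.
Verification compares candidate wells against control wells with a one-sided
Welch t-test (alternative: candidate < control); a mimic is verified when its
mean relative activity is below 1 and p < alpha.  No multiple-testing
correction is applied at verification (raw p < 0.05 is the reported rule).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .result import ScreenResult, make_screen_result
from .synthetic_data import AR_SIRNA, CONTROL_SIRNA


def _as_ids(control_id) -> list[str]:
    return [control_id] if isinstance(control_id, str) else list(control_id)


def _reporter_ratios(plate: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well firefly/Renilla ratios; wells with Renilla <= 0 are dropped."""
    piv = plate[plate["assay"].str.startswith("reporter_")].pivot_table(
        index=["plate_id", "well", "mimic_id"],
        columns="assay",
        values="luminescence",
        aggfunc="first",
    )
    for col in ("reporter_firefly", "reporter_renilla"):
        if col not in piv.columns:
            raise ValueError(f"plate table lacks {col} readings")
    bad = piv["reporter_renilla"] <= 0
    dropped = piv[bad].reset_index()[["plate_id", "well", "mimic_id"]]
    dropped["reason"] = "nonpositive_renilla"
    piv = piv[~bad]
    ratios = (piv["reporter_firefly"] / piv["reporter_renilla"]).rename("ratio")
    return ratios.reset_index(), dropped


def _per_sample_fc(
    values: pd.DataFrame,
    control_ids: list[str],
    value_col: str,
    raw_label: str,
) -> ScreenResult:
    by = values.groupby("mimic_id")[value_col]
    means, counts = by.mean(), by.size()
    ctrl_wells = values[values["mimic_id"].isin(control_ids)][value_col]
    if ctrl_wells.empty or ctrl_wells.mean() <= 0:
        raise ValueError("no usable control wells")
    control_mean = float(ctrl_wells.mean())

    fc_all = means / control_mean
    reference_ids = set(control_ids) | {CONTROL_SIRNA, AR_SIRNA}
    lib_ids = [i for i in fc_all.index if i not in reference_ids]
    fc = fc_all.loc[lib_ids]
    bad = fc <= 0
    removed = pd.DataFrame(
        {"reason": "nonpositive_signal"}, index=fc.index[bad]
    ).rename_axis("mimic_id")
    fc = fc[~bad]
    extra = pd.DataFrame(
        {raw_label: means.loc[fc.index], "n_wells": counts.loc[fc.index]}
    )
    result = make_screen_result(
        fc,
        extra=extra,
        control_ids=control_ids,
        control_mean=control_mean,
        reference_fc={
            i: float(fc_all[i]) for i in fc_all.index if i not in lib_ids
        },
    )
    result.removed = removed
    result.meta["fraction_below_control"] = (
        float((result.table["fc"] < 1.0).mean()) if len(result.table) else 0.0
    )
    return result


def renilla_normalize(plate: pd.DataFrame, control_id) -> ScreenResult:
    """Renilla-normalized reporter activity as fold change vs control mimic.

    Wells with non-positive Renilla are dropped (flagged); a mimic whose wells
    are all dropped is removed.  siRNA reference wells are excluded from the
    ranked table; their fold changes appear in ``meta['reference_fc']``.
    """
    control_ids = _as_ids(control_id)
    ratios, dropped_wells = _reporter_ratios(plate)
    result = _per_sample_fc(ratios, control_ids, "ratio", "mean_ratio")
    all_ids = set(plate["mimic_id"])
    no_wells = sorted(
        i
        for i in all_ids - set(ratios["mimic_id"])
        if i not in control_ids
    )
    if no_wells:
        extra_removed = pd.DataFrame(
            {"reason": "all_wells_dropped"}, index=pd.Index(no_wells, name="mimic_id")
        )
        result.removed = pd.concat([result.removed, extra_removed])
    result.meta["dropped_wells"] = int(len(dropped_wells))
    return result


def mluc_viability(plate: pd.DataFrame, control_id) -> ScreenResult:
    """MLuc viability fold change vs control mimic (single-channel wells)."""
    control_ids = _as_ids(control_id)
    wells = plate[plate["assay"] == "mluc"].rename(columns={"luminescence": "mluc"})
    if wells.empty:
        raise ValueError("plate table has no mluc readings")
    return _per_sample_fc(wells, control_ids, "mluc", "mean_mluc")


def _welch_one_sided_less(a: np.ndarray, b: np.ndarray) -> float:
    """p value for H1: mean(a) < mean(b); degenerate zero-variance cases are
    resolved by the sign of the mean difference."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0 if a.mean() < b.mean() else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False, alternative="less").pvalue)


def verify_suppression(
    plate: pd.DataFrame,
    candidate_ids: Sequence[str],
    control_id,
    alpha: float = 0.05,
    assay: str = "reporter",
) -> pd.DataFrame:
    """Suppression verification of candidates against control wells.

    For each candidate: mean relative activity (control = 1), its standard
    error, the one-sided Welch t-test p value (candidate < control), and
    ``verified = (mean < 1) & (p < alpha)``.  Requires >= 2 wells per group.

    The t statistic is computed on log-transformed Renilla-normalized ratios
    (or MLuc readings): luminescence noise is multiplicative, and the log
    scale keeps the one-sided test at its nominal size; the reported mean
    relative activity and its standard error stay on the linear scale.
    Non-positive well values cannot be log-transformed and are dropped.
    """
    control_ids = _as_ids(control_id)
    if assay == "reporter":
        values, _ = _reporter_ratios(plate)
        col = "ratio"
    elif assay == "mluc":
        values = plate[plate["assay"] == "mluc"].rename(
            columns={"luminescence": "mluc"}
        )
        col = "mluc"
    else:
        raise ValueError(f"unknown assay {assay!r}")

    values = values[values[col] > 0]
    ctrl = values[values["mimic_id"].isin(control_ids)][col].to_numpy(float)
    if len(ctrl) < 2:
        raise ValueError("verification requires >= 2 control wells")
    ctrl_mean = ctrl.mean()

    rows = []
    for cid in candidate_ids:
        cand = values[values["mimic_id"] == cid][col].to_numpy(float)
        if len(cand) < 2:
            raise ValueError(f"candidate {cid!r} has < 2 wells")
        rel = cand / ctrl_mean
        p = _welch_one_sided_less(np.log(cand), np.log(ctrl))
        mean_rel = float(rel.mean())
        rows.append(
            {
                "mimic_id": cid,
                "mean_relative_activity": mean_rel,
                "se": float(rel.std(ddof=1) / np.sqrt(len(rel))),
                "p_value": p,
                "verified": bool(mean_rel < 1.0 and p < alpha),
                "n_wells": len(cand),
            }
        )
    return pd.DataFrame(rows).set_index("mimic_id")
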