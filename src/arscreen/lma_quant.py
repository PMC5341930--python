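"""Lysate microarray (LMA) quantification.

Turns spot-level intensities (mimic x channel x dilution x triplicate) into
per-mimic GAPDH-normalized fold changes relative to the negative-control
mimics, reproducing the screen's quantification rules: a single dilution
within the linear range is selected per slide and channel, triplicate spots
are aggregated by median, signals are GAPDH-normalized, expressed as fold
change vs the mean control-mimic signal on the same slide, mimics with a
non-positive raw intensity in either channel are removed, and mimics are
ranked ascending by fold change (most suppressive first).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .result import ScreenResult, make_screen_result
from .synthetic_data import CONTROL_LYSATES

#: replicate coefficient of variation above which a mimic is flagged (retained)
HIGH_CV_THRESHOLD = 0.25

#: a dilution is considered saturated when its median intensity reaches this
#: fraction of the slide's maximum observed intensity
SATURATION_GUARD = 0.9


class SaturationError(RuntimeError):
    """All dilutions of a slide failed the saturation guard."""


def _origin_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a through-origin linear fit of y on x.

    A single point cannot demonstrate dilution linearity and scores -inf, so
    candidates with an assessable (>= 2 step) series always win over the most
    dilute step.
    """
    if len(x) < 2:
        return -np.inf
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def select_linear_dilution(
    spots: pd.DataFrame,
    channel: str,
    control_lysate_ids: tuple[str, ...] = CONTROL_LYSATES,
) -> float:
    """Pick the single dilution used for quantification of a slide/channel.

    Dilutions whose slide-wide median intensity reaches ``SATURATION_GUARD``
    of the slide's maximum observed intensity are excluded (detector-ceiling
    guard).  Among the remainder, the dilution maximizing the through-origin
    R^2 of median negative-control-lysate intensity vs nominal dilution factor
    — computed over that dilution and all more-dilute steps — wins; ties go to
    the more concentrated dilution.
    """
    ch = spots[spots["channel"] == channel]
    if ch.empty:
        raise ValueError(f"no spots for channel {channel!r}")
    dilutions = sorted(ch["dilution_factor"].unique(), reverse=True)
    if len(dilutions) < 2:
        raise ValueError("select_linear_dilution requires >= 2 dilutions")
    slide = ",".join(map(str, sorted(ch["slide_id"].unique())))

    med = ch.groupby("dilution_factor")["intensity"].median()
    ceiling = SATURATION_GUARD * float(ch["intensity"].max())
    usable = [d for d in dilutions if med[d] < ceiling]
    if not usable:
        raise SaturationError(f"all dilutions saturated on slide(s) {slide}")
    if len(usable) == 1:
        return float(usable[0])

    ctrl = ch[ch["mimic_id"].isin(control_lysate_ids)]
    if ctrl.empty:
        raise ValueError(f"no control-lysate spots on slide(s) {slide}")
    ctrl_med = ctrl.groupby("dilution_factor")["intensity"].median()

    best: tuple[float, float] | None = None
    for d in usable:
        series = [x for x in usable if x <= d]
        r2 = _origin_r2(
            np.asarray(series, float), ctrl_med.reindex(series).to_numpy(float)
        )
        if best is None or r2 > best[0] + 1e-9 or (abs(r2 - best[0]) <= 1e-9 and d > best[1]):
            best = (r2, float(d))
    return best[1]


def quantify(spots: pd.DataFrame, dilution: float) -> pd.DataFrame:
    """Aggregate triplicate spots at the chosen dilution, per mimic.

    Returns a DataFrame indexed by mimic_id with ``raw_target`` and
    ``raw_gapdh`` (medians of <=3 replicates) and a ``high_cv`` flag set when
    the target-channel replicate CV (sd/mean) exceeds ``HIGH_CV_THRESHOLD``.
    """
    at = spots[np.isclose(spots["dilution_factor"], dilution)]
    if at.empty:
        raise ValueError(f"no spots at dilution {dilution}")
    channels = sorted(at["channel"].unique())
    targets = [c for c in channels if c != "GAPDH"]
    if len(targets) != 1 or "GAPDH" not in channels:
        raise ValueError(f"expected one target channel plus GAPDH, got {channels}")
    target = targets[0]

    piv = at.pivot_table(
        index="mimic_id", columns="channel", values="intensity", aggfunc="median"
    )
    out = pd.DataFrame(
        {"raw_target": piv[target], "raw_gapdh": piv["GAPDH"]}
    ).rename_axis("mimic_id")

    grp = at[at["channel"] == target].groupby("mimic_id")["intensity"]
    mean, sd = grp.mean(), grp.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean).where(mean > 0)
    out["high_cv"] = (cv > HIGH_CV_THRESHOLD).reindex(out.index).fillna(False)
    out.attrs["dilution"] = float(dilution)
    out.attrs["target_channel"] = target
    return out


def normalize_and_fc(
    quantified: pd.DataFrame,
    control_mimic_ids,
    control_lysate_ids: tuple[str, ...] = CONTROL_LYSATES,
) -> ScreenResult:
    """GAPDH-normalize and express as fold change vs control mimics.

    ``norm_signal = raw_target / raw_gapdh``; ``fc`` divides by the arithmetic
    mean of control-mimic norm_signals on the same slide.  Mimics with a
    non-positive raw intensity in either channel are removed (flagged
    ``negative_removed``); control mimics and control lysates are excluded
    from the ranked table (the control mean is recorded in ``meta``).
    """
    control_mimic_ids = list(control_mimic_ids)
    q = quantified.drop(index=[i for i in control_lysate_ids if i in quantified.index])
    bad = (q["raw_target"] <= 0) | (q["raw_gapdh"] <= 0)
    removed = pd.DataFrame({"reason": "negative_removed"}, index=q.index[bad])
    removed.index.name = "mimic_id"
    q = q[~bad].copy()
    q["norm_signal"] = q["raw_target"] / q["raw_gapdh"]

    ctrl = q.loc[[i for i in control_mimic_ids if i in q.index], "norm_signal"]
    if ctrl.empty or ctrl.mean() <= 0:
        raise ValueError("no control mimic with positive normalized signal")
    control_mean = float(ctrl.mean())

    lib = q.drop(index=[i for i in control_mimic_ids if i in q.index])
    if lib.empty:
        raise ValueError("all library mimics removed")
    fc = lib["norm_signal"] / control_mean
    result = make_screen_result(
        fc,
        extra=lib[["raw_target", "raw_gapdh", "norm_signal", "high_cv"]],
        control_mimic_ids=control_mimic_ids,
        control_mean_norm_signal=control_mean,
        n_removed=int(bad.sum()),
        dilution=quantified.attrs.get("dilution"),
        target_channel=quantified.attrs.get("target_channel"),
    )
    result.removed = removed
    return result


def waterfall(result: ScreenResult) -> tuple[pd.DataFrame, float]:
    """Mimics sorted ascending by fc, plus the fraction with fc < 1."""
    ordered = result.table.sort_values("rank")
    fraction_below = float((ordered["fc"] < 1.0).mean()) if len(ordered) else 0.0
    result.meta["fraction_below_control"] = fraction_below
    return ordered, fraction_below


def quantify_slide(
    spots: pd.DataFrame,
    channel: str,
    control_mimic_ids,
    control_lysate_ids: tuple[str, ...] = CONTROL_LYSATES,
) -> ScreenResult:
    """Full LMA pipeline for one slide: dilution selection -> quantify ->
    normalize -> fold change."""
    dilution = select_linear_dilution(spots, channel, control_lysate_ids)
    ch_spots = spots[spots["channel"].isin([channel, "GAPDH"])]
    quantified = quantify(ch_spots, dilution)
    result = normalize_and_fc(quantified, control_mimic_ids, control_lysate_ids)
    waterfall(result)
    return result
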