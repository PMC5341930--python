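"""Shared per-mimic screen result container.

Every screen (LMA protein, luciferase reporter, MLuc viability) reduces to a
per-mimic table of normalized fold changes relative to the negative-control
mimic, plus a record of mimics removed by QC rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every ScreenResult table carries, in export order
CORE_COLUMNS = ("fc", "log2_fc", "rank")


@dataclass
class ScreenResult:
    """Per-mimic normalized fold changes for one assay / cell line.

    ``table`` is indexed by mimic_id and always contains ``fc`` (linear fold
    change vs control mimics), ``log2_fc`` and ``rank`` (ascending by fc, most
    suppressive first, ties broken lexicographically by mimic_id); assays add
    their own raw-signal columns.  ``removed`` lists mimics dropped by QC
    (negative raw intensity, no usable wells) with a ``reason`` column.
    ``meta`` records normalization provenance (chosen dilution, control ids,
    control mean, fraction below control).
    """

    table: pd.DataFrame
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"]).rename_axis("mimic_id")
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("fc", "log2_fc"):
            if col not in self.table.columns:
                raise ValueError(f"ScreenResult table lacks required column {col!r}")
        if len(self.table):
            fc = self.table["fc"].to_numpy(float)
            if not (fc > 0).all():
                raise ValueError("ScreenResult invariant violated: fc must be > 0")
        if "rank" not in self.table.columns:
            self.table = assign_ranks(self.table)

    @property
    def mimic_ids(self) -> pd.Index:
        return self.table.index

    def retained(self) -> int:
        return len(self.table)


def assign_ranks(table: pd.DataFrame) -> pd.DataFrame:
    """Rank mimics ascending by fc (rank 1 = most suppressive), ties by id."""
    order = table.assign(_id=table.index.astype(str)).sort_values(
        ["fc", "_id"], kind="mergesort"
    )
    out = table.loc[order.index].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def make_screen_result(
    fc: pd.Series, extra: pd.DataFrame | None = None, **meta
) -> ScreenResult:
    """Build a ScreenResult from a positive fc Series indexed by mimic_id."""
    tab = pd.DataFrame({"fc": fc.astype(float)})
    tab["log2_fc"] = np.log2(tab["fc"])
    if extra is not None:
        tab = extra.join(tab, how="right")[list(extra.columns) + ["fc", "log2_fc"]]
    tab = assign_ranks(tab)
    tab.index.name = "mimic_id"
    return ScreenResult(table=tab, meta=dict(meta))
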