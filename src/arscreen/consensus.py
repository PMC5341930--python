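"""Cross-assay, cross-cell-line consensus candidate selection.

The selection rule mirrors the screen's published procedure: the top 25% most
suppressive mimics (smallest fold change) are taken from every screen and
cell line; the candidate core is the set of mimics in the top quartile of the
AR-activity screen AND in the top quartile of the AR-protein LMA in at least
two cell lines AND of the PSA-protein LMA in at least two cell lines; a fixed
number of additional candidates is appended from the most potent AR-activity
inhibitors not already selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .result import ScreenResult

PROTEIN_ASSAYS = ("AR_protein", "PSA_protein")


@dataclass
class ScreenPanel:
    """Mapping (assay, cell_line) -> ScreenResult for one mimic library."""

    results: dict[tuple[str, str], ScreenResult]

    def cell_lines(self, assay: str) -> list[str]:
        return sorted(c for (a, c) in self.results if a == assay)

    def __getitem__(self, key: tuple[str, str]) -> ScreenResult:
        return self.results[key]


@dataclass
class CandidateSet:
    """Consensus candidates with per-screen evidence.

    ``core`` is ordered by AR-activity rank; ``extras`` are the most potent
    AR-activity inhibitors outside the core.  ``evidence`` is a boolean
    mimic x screen top-quartile membership matrix covering core and extras.
    """

    core: list[str]
    extras: list[str]
    evidence: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def candidates(self) -> list[str]:
        return self.core + self.extras


def top_fraction(result: ScreenResult, fraction: float) -> set[str]:
    """The floor(fraction * N_retained) mimics with smallest fold change.

    Ties broken lexicographically by mimic_id (the rank order already encodes
    both rules).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(result.table)
    if n == 0:
        raise ValueError("screen result is empty after removals")
    k = math.floor(fraction * n)
    ranked = result.table.sort_values("rank")
    return set(ranked.index[:k])


def select_candidates(
    panel: ScreenPanel,
    fraction: float = 0.25,
    min_cell_lines: int = 2,
    n_extra: int = 5,
    joint_cell_line_rule: bool = False,
) -> CandidateSet:
    """Apply the consensus rule to a screen panel.

    With ``joint_cell_line_rule`` the protein requirement becomes: at least
    ``min_cell_lines`` cell lines in which the mimic is top-quartile in both
    protein assays jointly (instead of each assay counting its cell lines
    independently).
    """
    activity_cells = panel.cell_lines("AR_activity")
    if len(activity_cells) != 1:
        raise ValueError(
            f"panel must contain AR_activity for exactly one cell line, "
            f"got {activity_cells}"
        )
    for assay in PROTEIN_ASSAYS:
        if len(panel.cell_lines(assay)) < min_cell_lines:
            raise ValueError(f"panel lacks {assay} in >= {min_cell_lines} cell lines")

    activity = panel[("AR_activity", activity_cells[0])]
    tops: dict[tuple[str, str], set[str]] = {
        key: top_fraction(res, fraction) for key, res in panel.results.items()
    }
    act_top = tops[("AR_activity", activity_cells[0])]

    def protein_ok(mimic: str) -> bool:
        if joint_cell_line_rule:
            cells = sorted(
                set(panel.cell_lines("AR_protein"))
                & set(panel.cell_lines("PSA_protein"))
            )
            n_joint = sum(
                mimic in tops[("AR_protein", c)] and mimic in tops[("PSA_protein", c)]
                for c in cells
            )
            return n_joint >= min_cell_lines
        return all(
            sum(mimic in tops[(assay, c)] for c in panel.cell_lines(assay))
            >= min_cell_lines
            for assay in PROTEIN_ASSAYS
        )

    act_rank = activity.table["rank"]
    core = sorted(
        (m for m in act_top if protein_ok(m)), key=lambda m: int(act_rank[m])
    )
    extras = [
        m
        for m in act_rank.sort_values().index
        if m not in core
    ][:n_extra]

    keys = sorted(tops)
    members = core + extras
    evidence = pd.DataFrame(
        {f"{a}|{c}": [m in tops[(a, c)] for m in members] for a, c in keys},
        index=pd.Index(members, name="mimic_id"),
    )
    return CandidateSet(
        core=core,
        extras=extras,
        evidence=evidence,
        provenance={
            "rule": "joint" if joint_cell_line_rule else "per_assay",
            "fraction": fraction,
            "min_cell_lines": min_cell_lines,
            "n_extra": n_extra,
        },
    )


def evidence_heatmap_table(panel: ScreenPanel, candidates: list[str]) -> pd.DataFrame:
    """Linear fold changes (candidate x screen); removed mimics are NaN."""
    cols = {}
    for (assay, cell) in sorted(panel.results):
        fc = panel[(assay, cell)].table["fc"]
        cols[f"{assay}|{cell}"] = fc.reindex(candidates)
    out = pd.DataFrame(cols, index=pd.Index(candidates, name="mimic_id"))
    return out


def cross_screen_correlation(
    a: ScreenResult, b: ScreenResult
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes over shared retained mimics."""
    shared = a.table.index.intersection(b.table.index)
    n = len(shared)
    if n < 3:
        raise ValueError("need >= 3 shared retained mimics")
    r, p = stats.pearsonr(
        a.table.loc[shared, "log2_fc"].to_numpy(float),
        b.table.loc[shared, "log2_fc"].to_numpy(float),
    )
    return float(r), float(p), n


def expected_null_core_size(panel: ScreenPanel, fraction: float = 0.25,
                            min_cell_lines: int = 2) -> float:
    """Closed-form expected core size when all screens are independent.

    Uses each screen's actual top-quartile membership probability
    floor(fraction*N)/N and a binomial >= min_cell_lines rule per protein
    assay.
    """
    activity_cells = panel.cell_lines("AR_activity")
    act = panel[("AR_activity", activity_cells[0])]
    n_act = len(act.table)
    p_act = math.floor(fraction * n_act) / n_act

    def assay_prob(assay: str) -> float:
        probs = []
        for c in panel.cell_lines(assay):
            n = len(panel[(assay, c)].table)
            probs.append(math.floor(fraction * n) / n)
        total = 0.0
        m = len(probs)
        for mask in range(2**m):
            bits = [(mask >> i) & 1 for i in range(m)]
            if sum(bits) < min_cell_lines:
                continue
            term = 1.0
            for b, p in zip(bits, probs):
                term *= p if b else (1 - p)
            total += term
        return total

    universe = act.table.index
    return len(universe) * p_act * np.prod(
        [assay_prob(a) for a in PROTEIN_ASSAYS]
    )
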