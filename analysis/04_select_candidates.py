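#!/usr/bin/env python
"""Consensus candidate selection across assays and cell lines.

Loads the six LMA screens plus the activity and viability screens, applies
the top-25% / >=2-cell-line consensus rule with 5 most-potent-activity
extras, reports the cross-screen AR/PSA correlations, and scores the
selected core against the planted truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from arscreen import consensus, io
from arscreen.result import ScreenResult
from arscreen.synthetic_data import ScreenSimConfig

CELLS = ("LNCaP", "VCaP", "LAPC4")


def load_panel(screens_dir: Path, activity_cell: str) -> consensus.ScreenPanel:
    results = {}
    for assay, cells in (
        ("AR_protein", CELLS),
        ("PSA_protein", CELLS),
        ("AR_activity", (activity_cell,)),
        ("viability", (activity_cell,)),
    ):
        for cell in cells:
            df, _ = io.read_tsv(screens_dir / f"screen_{assay}_{cell}.tsv")
            results[(assay, cell)] = ScreenResult(table=df.set_index("mimic_id"))
    return consensus.ScreenPanel(results)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--screens", type=Path, default=Path("results/screens"))
    ap.add_argument("--out", type=Path, default=Path("results/candidates"))
    ap.add_argument("--fraction", type=float, default=0.25)
    ap.add_argument("--min-cell-lines", type=int, default=2)
    ap.add_argument("--n-extra", type=int, default=5)
    args = ap.parse_args()

    panel = load_panel(args.screens, ScreenSimConfig().activity_cell_line)
    cand = consensus.select_candidates(
        panel, args.fraction, args.min_cell_lines, args.n_extra
    )
    heat = consensus.evidence_heatmap_table(panel, cand.candidates)
    io.write_tsv(
        pd.DataFrame(
            {
                "mimic_id": cand.candidates,
                "tier": ["core"] * len(cand.core) + ["extra"] * len(cand.extras),
            }
        ),
        args.out / "candidates.tsv",
        cand.provenance,
    )
    io.write_tsv(cand.evidence.reset_index(), args.out / "candidate_evidence.tsv")
    io.write_tsv(heat.reset_index(), args.out / "candidate_fc_heatmap.tsv")

    print(f"core candidates: {len(cand.core)}; extras: {len(cand.extras)}")
    for cell in CELLS:
        r, p, n = consensus.cross_screen_correlation(
            panel[("AR_protein", cell)], panel[("PSA_protein", cell)]
        )
        print(f"AR vs PSA protein log2 FC, {cell}: Pearson r = {r:.3f} (p = {p:.2g}, n = {n})")

    truth = json.loads((args.data / "planted_truth.json").read_text())
    hits = set(truth["true_suppressors"])
    core = set(cand.core)
    print(
        f"vs planted truth: precision {len(core & hits) / len(core):.2f}, "
        f"recall {len(core & hits) / len(hits):.2f}"
    )


if __name__ == "__main__":
    main()
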