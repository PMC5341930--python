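#!/usr/bin/env python
"""Normalize the reporter and viability plate screens.

Renilla-normalizes the AR transcriptional-activity reporter, averages MLuc
viability wells, expresses both as fold change vs the control mimics, and
writes the two remaining screen tables under results/screens/.
"""

import argparse
from pathlib import Path

from arscreen import assay_norm, io
from arscreen.synthetic_data import AR_SIRNA, ScreenSimConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/screens"))
    args = ap.parse_args()
    cfg = ScreenSimConfig()
    controls = cfg.control_mimic_ids()

    reporter, _ = io.read_plate_table(args.data / "plate_reporter.tsv")
    rep = assay_norm.renilla_normalize(reporter, controls)
    io.write_tsv(rep.table.reset_index(), args.out / f"screen_AR_activity_{cfg.activity_cell_line}.tsv")
    print(
        f"AR activity: {100 * rep.meta['fraction_below_control']:.0f}% of mimics "
        f"below control; AR-siRNA control fc = {rep.meta['reference_fc'][AR_SIRNA]:.3f}"
    )

    viability, _ = io.read_plate_table(args.data / "plate_viability.tsv")
    via = assay_norm.mluc_viability(viability, controls)
    io.write_tsv(via.table.reset_index(), args.out / f"screen_viability_{cfg.activity_cell_line}.tsv")
    print(
        f"viability:   {100 * via.meta['fraction_below_control']:.0f}% of mimics "
        "below control"
    )


if __name__ == "__main__":
    main()
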