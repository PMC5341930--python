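import numpy as np
import pandas as pd
import pytest

from arscreen import assay_norm, consensus, lma_quant
from arscreen import synthetic_data as sim


def build_full_panel(cfg: sim.ScreenSimConfig):
    """Simulate all four screens and quantify them into a ScreenPanel."""
    controls = cfg.control_mimic_ids()
    results = {}
    truth = None
    for channel, assay in (("AR", "AR_protein"), ("PSA", "PSA_protein")):
        tables, truth = sim.simulate_lma_screen(cfg, channel)
        for cell, spots in tables.items():
            results[(assay, cell)] = lma_quant.quantify_slide(spots, channel, controls)
    reporter, _ = sim.simulate_reporter_screen(cfg)
    viability, _ = sim.simulate_viability_screen(cfg)
    results[("AR_activity", cfg.activity_cell_line)] = assay_norm.renilla_normalize(
        reporter, controls
    )
    results[("viability", cfg.activity_cell_line)] = assay_norm.mluc_viability(
        viability, controls
    )
    return consensus.ScreenPanel(results), truth


def zero_effect_config(seed: int, **overrides) -> sim.ScreenSimConfig:
    """Config whose mimics all have latent effect exactly 0 (type-I studies)."""
    kw = dict(
        n_true_suppressors=0,
        inter_assay_rho=0.0,
        shared_effect_sd=0.0,
        cell_effect_sd=0.0,
        global_shift=0.0,
        negative_fraction=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return sim.ScreenSimConfig(**kw)


@pytest.fixture
def small_noise_free():
    """Small noise-free screen config with one strong planted suppressor."""
    return sim.ScreenSimConfig(
        n_mimics=20,
        n_true_suppressors=1,
        suppressor_effect=-2.0,
        global_shift=0.0,
        inter_assay_rho=0.45,
        shared_effect_sd=0.0,
        cell_effect_sd=0.0,
        spot_cv=0.0,
        negative_fraction=0.0,
        seed=11,
    )


def make_spot_table(rows) -> pd.DataFrame:
    """rows: (mimic_id, channel, dilution, replicate, intensity)."""
    return pd.DataFrame(
        [
            {
                "slide_id": "S1",
                "cell_line": "LNCaP",
                "mimic_id": m,
                "channel": c,
                "dilution_factor": d,
                "replicate": r,
                "intensity": x,
            }
            for m, c, d, r, x in rows
        ]
    )
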