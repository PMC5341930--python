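"""Reporter/viability normalization and suppression verification."""

import math

import numpy as np
import pandas as pd
import pytest

from arscreen import assay_norm
from arscreen import synthetic_data as sim
from conftest import zero_effect_config


def make_plate(samples, assays=("reporter_firefly", "reporter_renilla")):
    """samples: {id: {assay: [well values]}}."""
    rows = []
    for sid, per_assay in samples.items():
        n = len(next(iter(per_assay.values())))
        for r in range(n):
            for assay in assays:
                rows.append(
                    {
                        "plate_id": "P1",
                        "well": f"{sid}_{r + 1}",
                        "mimic_id": sid,
                        "assay": assay,
                        "replicate": r + 1,
                        "luminescence": per_assay[assay][r],
                    }
                )
    return pd.DataFrame(rows)


def welch_one_sided_oracle(a, b):
    """Textbook Welch t-test, H1: mean(a) < mean(b)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return tdist.cdf(t, df)


class TestRenillaNormalize:
    def test_uniform_ratio_gives_fc_one(self):
        plate = make_plate(
            {
                "m1": {"reporter_firefly": [200.0] * 3, "reporter_renilla": [100.0] * 3},
                "ctrl": {"reporter_firefly": [200.0] * 3, "reporter_renilla": [100.0] * 3},
            }
        )
        res = assay_norm.renilla_normalize(plate, "ctrl")
        assert res.table.loc["m1", "fc"] == pytest.approx(1.0)

    def test_halved_firefly_gives_fc_half(self):
        plate = make_plate(
            {
                "m1": {"reporter_firefly": [100.0] * 3, "reporter_renilla": [100.0] * 3},
                "ctrl": {"reporter_firefly": [200.0] * 3, "reporter_renilla": [100.0] * 3},
            }
        )
        res = assay_norm.renilla_normalize(plate, "ctrl")
        assert res.table.loc["m1", "fc"] == pytest.approx(0.5)

    def test_ar_sirna_noise_free_eighth(self):
        cfg = zero_effect_config(seed=13, n_mimics=10, spot_cv=0.0)
        plate, _ = sim.simulate_reporter_screen(cfg)
        res = assay_norm.renilla_normalize(plate, cfg.control_mimic_ids())
        assert res.meta["reference_fc"][sim.AR_SIRNA] == pytest.approx(0.125)

    def test_nonpositive_renilla_well_dropped(self):
        plate = make_plate(
            {
                "m1": {
                    "reporter_firefly": [100.0, 100.0, 100.0],
                    "reporter_renilla": [100.0, 0.0, 100.0],
                },
                "ctrl": {"reporter_firefly": [100.0] * 3, "reporter_renilla": [100.0] * 3},
            }
        )
        res = assay_norm.renilla_normalize(plate, "ctrl")
        assert res.meta["dropped_wells"] == 1
        assert res.table.loc["m1", "n_wells"] == 2

    def test_all_wells_dropped_removes_mimic(self):
        plate = make_plate(
            {
                "m1": {"reporter_firefly": [100.0] * 3, "reporter_renilla": [-1.0] * 3},
                "ctrl": {"reporter_firefly": [100.0] * 3, "reporter_renilla": [100.0] * 3},
            }
        )
        res = assay_norm.renilla_normalize(plate, "ctrl")
        assert "m1" not in res.table.index
        assert res.removed.loc["m1", "reason"] == "all_wells_dropped"

    def test_shared_scaling_invariance(self):
        plate = make_plate(
            {
                "m1": {"reporter_firefly": [150.0, 160.0, 140.0], "reporter_renilla": [100.0] * 3},
                "ctrl": {"reporter_firefly": [200.0, 190.0, 210.0], "reporter_renilla": [100.0] * 3},
            }
        )
        base = assay_norm.renilla_normalize(plate, "ctrl").table["fc"]
        scaled = plate.copy()
        scaled["luminescence"] *= 37.5
        res = assay_norm.renilla_normalize(scaled, "ctrl").table["fc"]
        assert np.allclose(res, base)


class TestMlucViability:
    def test_fc_vs_control(self):
        plate = make_plate(
            {
                "m1": {"mluc": [50.0] * 4},
                "ctrl": {"mluc": [100.0] * 4},
            },
            assays=("mluc",),
        )
        res = assay_norm.mluc_viability(plate, "ctrl")
        assert res.table.loc["m1", "fc"] == pytest.approx(0.5)

    def test_noise_free_inversion(self):
        cfg = sim.ScreenSimConfig(seed=21, spot_cv=0.0, negative_fraction=0.0)
        plate, truth = sim.simulate_viability_screen(cfg)
        res = assay_norm.mluc_viability(plate, cfg.control_mimic_ids())
        e = truth.effects[("viability", cfg.activity_cell_line)]
        assert np.allclose(res.table["fc"], 2.0 ** e.loc[res.table.index], rtol=1e-12)


class TestVerifySuppression:
    def _mluc_plate(self, cand, ctrl):
        return make_plate(
            {"cand": {"mluc": cand}, "ctrl": {"mluc": ctrl}}, assays=("mluc",)
        )

    def test_identical_groups_not_verified(self):
        plate = self._mluc_plate([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        ver = assay_norm.verify_suppression(plate, ["cand"], "ctrl", assay="mluc")
        row = ver.loc["cand"]
        assert row["mean_relative_activity"] == pytest.approx(1.0)
        assert row["p_value"] == 1.0
        assert not row["verified"]

    def test_clear_suppression_verified_with_welch_oracle(self):
        cand, ctrl = [0.4, 0.5, 0.45], [1.0, 1.05, 0.95]
        plate = self._mluc_plate(cand, ctrl)
        ver = assay_norm.verify_suppression(plate, ["cand"], "ctrl", assay="mluc")
        row = ver.loc["cand"]
        assert row["verified"]
        expected_p = welch_one_sided_oracle(np.log(cand), np.log(ctrl))
        assert row["p_value"] == pytest.approx(expected_p, rel=1e-9)
        assert row["mean_relative_activity"] == pytest.approx(0.45, rel=1e-9)

    def test_single_replicate_errors(self):
        plate = self._mluc_plate([0.5], [1.0, 1.0])
        with pytest.raises(ValueError, match="< 2 wells"):
            assay_norm.verify_suppression(plate, ["cand"], "ctrl", assay="mluc")

    def test_false_positive_rate_near_nominal(self):
        fp = total = 0
        for s in range(10):
            cfg = zero_effect_config(seed=40 + s, n_mimics=20)
            plate, _ = sim.simulate_reporter_screen(cfg, n_replicates=6)
            ver = assay_norm.verify_suppression(
                plate, cfg.mimic_ids(), cfg.control_mimic_ids()
            )
            fp += int(ver["verified"].sum())
            total += len(ver)
        assert fp / total <= 0.10  # 200 nulls; generous Monte-Carlo margin

    def test_power_monotone_in_effect_and_replicates(self):
        """Detection power grows with effect size and replication."""

        def power(effect, n_rep, seeds=range(15)):
            hits = 0
            for s in seeds:
                cfg = zero_effect_config(seed=60 + s, n_mimics=1)
                plate, _ = sim.simulate_reporter_screen(cfg, n_replicates=n_rep)
                mimic = cfg.mimic_ids()[0]
                mask = (plate["mimic_id"] == mimic) & (
                    plate["assay"] == "reporter_firefly"
                )
                plate.loc[mask, "luminescence"] *= 2.0**effect
                ver = assay_norm.verify_suppression(
                    plate, [mimic], cfg.control_mimic_ids()
                )
                hits += int(ver["verified"].iloc[0])
            return hits / 15

        assert power(0.0, 3) <= power(-0.5, 3) <= power(-2.0, 3)
        assert power(-0.5, 3) <= power(-0.5, 12)
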