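"""LMA quantification: dilution selection, aggregation, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arscreen import lma_quant
from arscreen import synthetic_data as sim
from conftest import make_spot_table


def _series_table(mimic_values, lysate_base=1000.0, dilutions=(1.0, 0.25, 0.0625),
                  clip=None):
    """Noise-free AR-channel dilution series for given per-mimic base values."""
    rows = []
    for d in dilutions:
        for r in (1, 2, 3):
            for m, v in mimic_values.items():
                x = v * d
                rows.append((m, "AR", d, r, min(x, clip) if clip else x))
            for lys in ("PC3", "DU145"):
                rows.append((lys, "AR", d, r, lysate_base * d))
    return make_spot_table(rows)


class TestSelectLinearDilution:
    MIMICS = {"m1": 8000.0, "m2": 4000.0, "m3": 2000.0, "m4": 1000.0}

    def test_noise_free_unsaturated_returns_most_concentrated(self):
        spots = _series_table(self.MIMICS)
        assert lma_quant.select_linear_dilution(spots, "AR") == 1.0

    def test_clipped_top_dilution_excluded(self):
        # every mimic clipped at 10000 at the 1:1 step -> median == max there
        mimics = {m: 30000.0 for m in ("m1", "m2", "m3", "m4")}
        spots = _series_table(mimics, clip=10000.0)
        assert lma_quant.select_linear_dilution(spots, "AR") == 0.25

    def test_single_usable_dilution_returned(self):
        mimics = {m: 30000.0 for m in ("m1", "m2", "m3", "m4")}
        spots = _series_table(mimics, dilutions=(1.0, 0.25), clip=10000.0)
        # 1:1 saturated (all spots at ceiling) leaves only the 1:4 step
        assert lma_quant.select_linear_dilution(spots, "AR") == 0.25

    def test_all_saturated_errors_with_slide_name(self):
        mimics = {m: 30000.0 for m in ("m1", "m2", "m3", "m4")}
        spots = _series_table(mimics, clip=100.0, lysate_base=99.0)
        with pytest.raises(lma_quant.SaturationError, match="S1"):
            lma_quant.select_linear_dilution(spots, "AR")

    def test_missing_control_lysates_error(self):
        spots = _series_table(self.MIMICS)
        spots = spots[~spots["mimic_id"].isin(("PC3", "DU145"))]
        with pytest.raises(ValueError, match="control-lysate"):
            lma_quant.select_linear_dilution(spots, "AR")

    def test_requires_two_dilutions(self):
        spots = _series_table(self.MIMICS, dilutions=(1.0,))
        with pytest.raises(ValueError, match="2 dilutions"):
            lma_quant.select_linear_dilution(spots, "AR")


class TestQuantify:
    @pytest.mark.parametrize(
        "reps,expected,high_cv",
        [
            ((10.0, 10.0, 10.0), 10.0, False),
            ((8.0, 10.0, 12.0), 10.0, False),
            ((1.0, 10.0, 100.0), 10.0, True),  # CV = sd/mean ~ 1.47
        ],
    )
    def test_median_aggregation_and_cv_flag(self, reps, expected, high_cv):
        rows = [("m1", "AR", 1.0, i + 1, v) for i, v in enumerate(reps)]
        rows += [("m1", "GAPDH", 1.0, i + 1, 10.0) for i in range(3)]
        q = lma_quant.quantify(make_spot_table(rows), 1.0)
        assert q.loc["m1", "raw_target"] == expected
        assert bool(q.loc["m1", "high_cv"]) is high_cv
        # oracle: textbook CV
        cv = np.std(reps, ddof=1) / np.mean(reps)
        assert bool(cv > 0.25) == high_cv


class TestNormalizeAndFc:
    def _quantified(self, target, gapdh, ids=None):
        ids = ids or [f"m{i}" for i in range(len(target))]
        df = pd.DataFrame(
            {"raw_target": target, "raw_gapdh": gapdh, "high_cv": False},
            index=pd.Index(ids, name="mimic_id"),
        )
        return df

    def test_uniform_half_signal_gives_fc_half(self):
        q = self._quantified([5.0, 5.0, 10.0], [10.0, 10.0, 10.0], ["m1", "m2", "ctrl"])
        res = lma_quant.normalize_and_fc(q, ["ctrl"])
        assert np.allclose(res.table["fc"], 0.5)
        assert np.allclose(res.table["log2_fc"], -1.0)

    def test_negative_target_removed_and_flagged(self):
        q = self._quantified([-3.0, 10.0, 10.0], [10.0, 10.0, 10.0], ["bad", "m2", "ctrl"])
        res = lma_quant.normalize_and_fc(q, ["ctrl"])
        assert "bad" not in res.table.index
        assert res.removed.loc["bad", "reason"] == "negative_removed"
        assert len(res.table) + len(res.removed) + 1 == 3  # +1 control

    def test_no_valid_controls_errors(self):
        q = self._quantified([10.0], [10.0], ["m1"])
        with pytest.raises(ValueError, match="control"):
            lma_quant.normalize_and_fc(q, ["ctrl"])

    def test_rank_ascending_ties_by_id(self):
        q = self._quantified(
            [5.0, 5.0, 2.0, 10.0], [10.0] * 4, ["mB", "mA", "mC", "ctrl"]
        )
        res = lma_quant.normalize_and_fc(q, ["ctrl"])
        assert list(res.table.sort_values("rank").index) == ["mC", "mA", "mB"]


class TestWaterfall:
    def test_fraction_below_control(self):
        q = pd.DataFrame(
            {
                "raw_target": [5.0, 9.0, 11.0, 20.0, 10.0],
                "raw_gapdh": [10.0] * 5,
                "high_cv": False,
            },
            index=pd.Index(["m1", "m2", "m3", "m4", "ctrl"], name="mimic_id"),
        )
        res = lma_quant.normalize_and_fc(q, ["ctrl"])
        ordered, frac = lma_quant.waterfall(res)
        assert frac == 0.5
        assert list(ordered["fc"]) == sorted(ordered["fc"])

    def test_all_at_control_level(self):
        q = pd.DataFrame(
            {"raw_target": [10.0] * 3, "raw_gapdh": [10.0] * 3, "high_cv": False},
            index=pd.Index(["m1", "m2", "ctrl"], name="mimic_id"),
        )
        _, frac = lma_quant.waterfall(lma_quant.normalize_and_fc(q, ["ctrl"]))
        assert frac == 0.0


class TestPipelineProperties:
    def test_noise_free_null_recovers_fc_one(self, small_noise_free):
        cfg = sim.ScreenSimConfig(
            **{**sim.asdict(small_noise_free), "n_true_suppressors": 0}
        )
        tables, _ = sim.simulate_lma_screen(cfg, "AR")
        res = lma_quant.quantify_slide(tables["LNCaP"], "AR", cfg.control_mimic_ids())
        assert np.allclose(res.table["fc"], 1.0)

    def test_planted_hit_recovered_exactly(self, small_noise_free):
        tables, truth = sim.simulate_lma_screen(small_noise_free, "AR")
        res = lma_quant.quantify_slide(
            tables["LNCaP"], "AR", small_noise_free.control_mimic_ids()
        )
        hit = truth.true_suppressors[0]
        assert res.table.loc[hit, "fc"] == pytest.approx(0.25, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100.0), per_mimic=st.floats(0.1, 10.0))
    def test_scale_and_gapdh_invariance(self, scale, per_mimic):
        """Slide-wide scaling and shared per-mimic channel factors leave fc fixed."""
        q = pd.DataFrame(
            {
                "raw_target": [5.0, 8.0, 10.0],
                "raw_gapdh": [10.0, 10.0, 10.0],
                "high_cv": False,
            },
            index=pd.Index(["m1", "m2", "ctrl"], name="mimic_id"),
        )
        base = lma_quant.normalize_and_fc(q, ["ctrl"]).table["fc"]
        q2 = q.copy()
        q2[["raw_target", "raw_gapdh"]] *= scale  # slide-wide rescale
        q2.loc["m1", ["raw_target", "raw_gapdh"]] *= per_mimic  # loading factor
        res2 = lma_quant.normalize_and_fc(q2, ["ctrl"]).table["fc"]
        assert np.allclose(res2, base, rtol=1e-9)

    def test_retained_plus_removed_equals_input(self):
        cfg = sim.ScreenSimConfig(seed=4, negative_fraction=0.05)
        tables, _ = sim.simulate_lma_screen(cfg, "AR")
        res = lma_quant.quantify_slide(tables["LNCaP"], "AR", cfg.control_mimic_ids())
        assert len(res.table) + len(res.removed) == cfg.n_mimics
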