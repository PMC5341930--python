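"""Whole-pipeline property benchmarks.

Each function runs one end-to-end property study on simulated data with
planted ground truth — the checks a practitioner would run to convince
themselves the pipeline behaves as designed: exact inversion of the
quantification chain on noise-free data, recovery of planted suppressors by
the consensus rule, chance-level behaviour under null conditions, calibrated
correlation machinery, and exact agreement of the seed scanner and the
BH-FDR filter with brute-force oracles.  All randomness flows from the
``seed`` argument.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from . import assay_norm, consensus, expression_stats, lma_quant, seed_scan
from . import synthetic_data as sim


def _seeds(seed: int, stream: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2^31 derived from (seed, stream)."""
    rng = np.random.default_rng([int(seed), stream])
    return [int(x) for x in rng.integers(0, 2**31 - 1, size=n)]


def build_full_panel(cfg: sim.ScreenSimConfig):
    """Simulate and quantify all four screens into a ScreenPanel."""
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
    """All mimics at latent effect exactly 0 (type-I error studies)."""
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


# -- 1. seed-scanner vs brute force -----------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def brute_force_sites(mirna, region):
    """Sliding-window enumeration of canonical sites (independent oracle)."""
    seq = region.sequence
    mir = mirna.sequence
    core = "".join(_COMP[mir[i]] for i in range(6, 0, -1))
    p8 = _COMP[mir[7]]
    patterns = {
        "8mer": p8 + core + "A",
        "7mer-m8": p8 + core,
        "7mer-A1": core + "A",
        "6mer": core,
    }
    candidates = []
    for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        pat = patterns[stype]
        for i in range(len(seq) - len(pat) + 1):
            if seq[i : i + len(pat)] == pat:
                candidates.append((stype, i + 1, i + len(pat)))
    order = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
    kept = []
    for stype, s, e in sorted(candidates, key=lambda c: (order[c[0]], c[1])):
        if all(e < ks or s > ke for _, ks, ke in kept):
            kept.append((stype, s, e))
    return sorted((s, e, t) for t, s, e in kept)


def scanner_oracle_agreement(seed: int, n_cases: int = 200, max_len: int = 2000):
    """Fraction of random (miRNA, region) cases where scan == brute force."""
    rng = np.random.default_rng([seed, 11])
    agree = 0
    for _ in range(n_cases):
        mirna = seed_scan.MatureMiRNA(
            "m", "".join(rng.choice(list("ACGU"), size=int(rng.integers(18, 27))))
        )
        region = seed_scan.TranscriptRegion(
            "r", "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, max_len + 1))))
        )
        got = sorted(
            (s.start, s.end, s.site_type) for s in seed_scan.scan_sites(mirna, region)
        )
        agree += int(got == brute_force_sites(mirna, region))
    return agree / n_cases


# -- 2. noise-free quantification inversion ----------------------------------

def quantification_inversion_error(seed: int) -> float:
    """Max relative error |recovered FC / 2^effect - 1| over all noise-free
    screens (LMA both channels x 3 cell lines, reporter, viability)."""
    cfg = sim.ScreenSimConfig(seed=seed, spot_cv=0.0, negative_fraction=0.0)
    controls = cfg.control_mimic_ids()
    worst = 0.0
    for channel, assay in (("AR", "AR_protein"), ("PSA", "PSA_protein")):
        tables, truth = sim.simulate_lma_screen(cfg, channel)
        for cell, spots in tables.items():
            res = lma_quant.quantify_slide(spots, channel, controls)
            e = truth.effects[(assay, cell)].loc[res.table.index]
            worst = max(worst, float(np.abs(res.table["fc"] / 2.0**e - 1).max()))
            assert len(res.table) == cfg.n_mimics
    reporter, truth = sim.simulate_reporter_screen(cfg)
    res = assay_norm.renilla_normalize(reporter, controls)
    e = truth.effects[("AR_activity", cfg.activity_cell_line)].loc[res.table.index]
    worst = max(worst, float(np.abs(res.table["fc"] / 2.0**e - 1).max()))
    viability, _ = sim.simulate_viability_screen(cfg)
    res = assay_norm.mluc_viability(viability, controls)
    e = truth.effects[("viability", cfg.activity_cell_line)].loc[res.table.index]
    worst = max(worst, float(np.abs(res.table["fc"] / 2.0**e - 1).max()))
    return worst


# -- 3. consensus recovery of planted suppressors ----------------------------

def consensus_recovery(seed: int, n_seeds: int = 10, suppressor_effect: float = -1.5):
    """Mean precision/recall of the candidate core vs planted truth."""
    precs, recs = [], []
    for s in _seeds(seed, 31, n_seeds):
        cfg = sim.ScreenSimConfig(seed=s, suppressor_effect=suppressor_effect)
        panel, truth = build_full_panel(cfg)
        core = set(consensus.select_candidates(panel).core)
        hits = set(truth.true_suppressors)
        precs.append(len(core & hits) / len(core) if core else 0.0)
        recs.append(len(core & hits) / len(hits))
    return float(np.mean(precs)), float(np.mean(recs))


# -- 4. null calibration ------------------------------------------------------

def null_core_calibration(seed: int, n_seeds: int = 20):
    """(mean observed null core size, closed-form expectation, 3x Poisson SEM)."""
    counts = []
    expected = None
    for s in _seeds(seed, 41, n_seeds):
        cfg = sim.null_independent_config(seed=s)
        panel, _ = build_full_panel(cfg)
        counts.append(len(consensus.select_candidates(panel).core))
        if expected is None:
            expected = consensus.expected_null_core_size(panel)
    tol = 3.0 * math.sqrt(expected / n_seeds)
    return float(np.mean(counts)), float(expected), tol


def verification_false_positive_rate(
    seed: int, n_nulls: int = 1000, candidates_per_plate: int = 20, n_wells: int = 6
):
    """Fraction of zero-effect mimics verified as suppressors at alpha=0.05."""
    n_plates = n_nulls // candidates_per_plate
    fp = total = 0
    for s in _seeds(seed, 43, n_plates):
        cfg = zero_effect_config(seed=s, n_mimics=candidates_per_plate)
        plate, _ = sim.simulate_reporter_screen(cfg, n_replicates=n_wells)
        ver = assay_norm.verify_suppression(
            plate, cfg.mimic_ids(), cfg.control_mimic_ids()
        )
        fp += int(ver["verified"].sum())
        total += len(ver)
    return fp / total


# -- 5. correlation machinery -------------------------------------------------

def cross_screen_r(seed: int, rho: float = 0.5) -> float:
    """Recovered AR/PSA Pearson r at latent inter-assay correlation ``rho``."""
    cfg = sim.ScreenSimConfig(seed=seed, inter_assay_rho=rho)
    controls = cfg.control_mimic_ids()
    ta, _ = sim.simulate_lma_screen(cfg, "AR")
    tp, _ = sim.simulate_lma_screen(cfg, "PSA")
    ra = lma_quant.quantify_slide(ta[cfg.activity_cell_line], "AR", controls)
    rp = lma_quant.quantify_slide(tp[cfg.activity_cell_line], "PSA", controls)
    return consensus.cross_screen_correlation(ra, rp)[0]


def cohort_negative_correlation_rate(
    seed: int, n_seeds: int = 500, coupling: float = -0.9
) -> float:
    """Fraction of cohort simulations with significant negative miR-30d/PSA
    Pearson correlation across CRPC samples."""
    hits = 0
    for s in _seeds(seed, 53, n_seeds):
        table, _ = sim.simulate_expression_cohort(coupling_strength=coupling, seed=s)
        groups = expression_stats.sample_groups(table)
        levels, _ = expression_stats.normalize_ddpcr(table)
        psa = expression_stats.relative_qpcr(table)
        crpc = groups[groups == "CRPC"].index
        r, p, _ = expression_stats.correlate(
            levels.loc[crpc, "miR-30d-5p"], psa.loc[crpc]
        )
        hits += int(r < 0 and p < 0.05)
    return hits / n_seeds


# -- 6. BH-FDR oracle ---------------------------------------------------------

def bh_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = min(running, 1.0)
    return q


def bh_max_oracle_difference(seed: int, n_cases: int = 100) -> float:
    rng = np.random.default_rng([seed, 61])
    worst = 0.0
    for _ in range(n_cases):
        p = rng.uniform(size=int(rng.integers(1, 80)))
        worst = max(
            worst, float(np.max(np.abs(expression_stats.bh_adjust(p) - bh_oracle(p))))
        )
    return worst


def allnull_pass_fraction(
    seed: int, n_seeds: int = 200, n_features: int = 100, n_per_group: int = 10
) -> float:
    """Mean fraction of all-null features passing the FDR+FC filter."""
    fracs = []
    for s in _seeds(seed, 63, n_seeds):
        rng = np.random.default_rng(s)
        expr = pd.DataFrame(
            rng.lognormal(sigma=0.3, size=(n_features, 2 * n_per_group)),
            columns=[f"s{i}" for i in range(2 * n_per_group)],
        )
        groups = pd.Series(
            ["normal"] * n_per_group + ["CRPC"] * n_per_group, index=expr.columns
        )
        out = expression_stats.de_filter(expr, groups)
        fracs.append(float(out["passes"].mean()))
    return float(np.mean(fracs))


# -- 7. mutagenesis contract --------------------------------------------------

def mutagenesis_contract_violations(seed: int, n_fixtures: int = 100) -> int:
    """Count of fixtures where site ablation removes the wrong site set."""
    rng = np.random.default_rng([seed, 71])
    types = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    violations = 0
    for s in _seeds(seed, 73, n_fixtures):
        n_sites = int(rng.integers(1, 4))
        positions = sorted(rng.choice(np.arange(10, 960, 15), n_sites, replace=False))
        planted = [
            (int(rng.integers(0, 2)), types[int(rng.integers(0, 4))], int(pos))
            for pos in positions
        ]
        mirnas, region, truth = sim.emit_sequences(
            n_mirnas=2, utr_length=1000, planted_sites=planted, seed=s
        )
        for victim in truth:
            mutated = seed_scan.mutate_site(region, victim)
            ok = True
            for m in mirnas:
                found = {
                    (x.start, x.end, x.site_type) for x in seed_scan.scan_sites(m, mutated)
                }
                kept_truth = {
                    (x.start, x.end, x.site_type)
                    for x in truth
                    if x.mirna_id == m.id
                    and not (x.start <= victim.end and victim.start <= x.end)
                }
                if m.id == victim.mirna_id:
                    # the victim site is gone; nothing overlapping its span remains
                    if any(s0 <= victim.end and victim.start <= e0 for s0, e0, _ in found):
                        ok = False
                if not kept_truth <= found:
                    ok = False
            violations += int(not ok)
    return violations


# -- 8. manifest determinism --------------------------------------------------

def pipeline_determinism(seed: int, outdir) -> bool:
    """Run the full pipeline twice; True iff manifests are byte-identical."""
    from .pipeline import PipelineConfig, run_pipeline
    from pathlib import Path

    outdir = Path(outdir)
    m1 = run_pipeline(PipelineConfig(outdir=str(outdir / "run1"), seed=seed))
    m2 = run_pipeline(PipelineConfig(outdir=str(outdir / "run2"), seed=seed))
    b1 = (outdir / "run1" / "manifest.json").read_bytes()
    b2 = (outdir / "run2" / "manifest.json").read_bytes()
    return json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True) and b1 == b2
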