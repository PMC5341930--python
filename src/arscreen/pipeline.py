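"""End-to-end pipeline driver: simulate -> quantify -> select -> verify ->
seed-scan -> cohort statistics, with a checksummed results manifest.

The pipeline is deterministic given (config, seed): every stage writes its
tables under the output directory and the manifest records parameters plus a
sha256 for each file (paths relative to the output directory, so manifests
from identical runs are byte-identical).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd

from . import assay_norm, consensus, expression_stats, io, lma_quant, seed_scan
from . import synthetic_data as sim

log = logging.getLogger("arscreen")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[arscreen] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-screen pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    fraction: float = 0.25
    min_cell_lines: int = 2
    n_extra: int = 5
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    min_fc: float = 1.2
    joint_cell_line_rule: bool = False
    n_verification_replicates: int = 6
    cohort_n_per_group: int = 15
    mir30d_crpc_log2_shift: float = -1.0
    coupling_strength: float = -0.6
    screen: dict = field(default_factory=dict)  # ScreenSimConfig overrides

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        if self.min_cell_lines < 1 or self.n_extra < 0:
            raise ValueError("min_cell_lines >= 1 and n_extra >= 0 required")
        for name in ("alpha", "fdr_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_fc < 1:
            raise ValueError("min_fc must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def screen_config(self) -> sim.ScreenSimConfig:
        return sim.ScreenSimConfig(seed=self.seed, **self.screen)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def default_amplicons(utr_length: int, n: int = 7) -> list[seed_scan.Amplicon]:
    """Illustrative AR1..AR7 overlapping amplicon tiling of a UTR."""
    step = utr_length // n
    size = int(step * 1.4)  # ~40% overlap with the next tile
    amps = []
    for i in range(n):
        start = max(1, i * step + 1)
        end = min(utr_length, start + size - 1)
        amps.append(seed_scan.Amplicon(name=f"AR{i + 1}", start=start, end=end))
    return amps


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    scfg = config.screen_config()
    controls = scfg.control_mimic_ids()

    def emit(df, name, meta=None, index=False):
        io.write_tsv(df, outdir / name, meta={"seed": config.seed, **(meta or {})}, index=index)
        written.append(name)

    # -- stage: simulate -----------------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        data = {}
        for channel in ("AR", "PSA"):
            tables, truth = sim.simulate_lma_screen(scfg, channel)
            for cell, df in tables.items():
                emit(df, f"spots_{channel}_{cell}.tsv", {"channel": channel})
            data[channel] = tables
        reporter, truth = sim.simulate_reporter_screen(scfg)
        viability, _ = sim.simulate_viability_screen(scfg)
        emit(reporter, "plate_reporter.tsv")
        emit(viability, "plate_viability.tsv")
        (outdir / "planted_truth.json").write_text(truth.to_json() + "\n")
        written.append("planted_truth.json")
        return data, reporter, viability, truth

    lma_tables, reporter_plate, viability_plate, truth = stage_simulate()

    # -- stage: lma ----------------------------------------------------------
    @_stage("lma")
    def stage_lma():
        results = {}
        for channel, assay in (("AR", "AR_protein"), ("PSA", "PSA_protein")):
            for cell, spots in lma_tables[channel].items():
                res = lma_quant.quantify_slide(spots, channel, controls)
                results[(assay, cell)] = res
                emit(
                    res.table.reset_index(),
                    f"screen_{assay}_{cell}.tsv",
                    {k: res.meta[k] for k in ("dilution", "fraction_below_control")},
                )
        return results

    screen_results = stage_lma()

    # -- stage: plates -------------------------------------------------------
    @_stage("plates")
    def stage_plates():
        rep = assay_norm.renilla_normalize(reporter_plate, controls)
        via = assay_norm.mluc_viability(viability_plate, controls)
        cell = scfg.activity_cell_line
        screen_results[("AR_activity", cell)] = rep
        screen_results[("viability", cell)] = via
        emit(rep.table.reset_index(), f"screen_AR_activity_{cell}.tsv")
        emit(via.table.reset_index(), f"screen_viability_{cell}.tsv")
        return rep, via

    stage_plates()

    # -- stage: consensus ----------------------------------------------------
    @_stage("consensus")
    def stage_consensus():
        panel = consensus.ScreenPanel(screen_results)
        cand = consensus.select_candidates(
            panel,
            fraction=config.fraction,
            min_cell_lines=config.min_cell_lines,
            n_extra=config.n_extra,
            joint_cell_line_rule=config.joint_cell_line_rule,
        )
        heat = consensus.evidence_heatmap_table(panel, cand.candidates)
        emit(
            pd.DataFrame(
                {
                    "mimic_id": cand.candidates,
                    "tier": ["core"] * len(cand.core) + ["extra"] * len(cand.extras),
                }
            ),
            "candidates.tsv",
            cand.provenance,
        )
        emit(cand.evidence.reset_index(), "candidate_evidence.tsv")
        emit(heat.reset_index(), "candidate_fc_heatmap.tsv")

        corr = {}
        for cell in scfg.cell_lines:
            r, p, n = consensus.cross_screen_correlation(
                screen_results[("AR_protein", cell)],
                screen_results[("PSA_protein", cell)],
            )
            corr[cell] = {"pearson_r": round(r, 6), "p_value": float(f"{p:.6g}"), "n": n}
        (outdir / "cross_screen_correlation.json").write_text(
            json.dumps(corr, indent=1, sort_keys=True) + "\n"
        )
        written.append("cross_screen_correlation.json")
        return cand

    candidates = stage_consensus()

    # -- stage: verify -------------------------------------------------------
    @_stage("verify")
    def stage_verify():
        plate, _ = sim.simulate_reporter_screen(
            scfg,
            n_replicates=config.n_verification_replicates,
            measurement_seed=scfg.seed + 1,
        )
        ids = [m for m in candidates.candidates if m in set(plate["mimic_id"])]
        ver = assay_norm.verify_suppression(plate, ids, controls, alpha=config.alpha)
        emit(ver.reset_index(), "verification.tsv", {"alpha": config.alpha})
        return ver

    stage_verify()

    # -- stage: seedscan -----------------------------------------------------
    @_stage("seedscan")
    def stage_seedscan():
        utr_len = 6900
        planted = [(0, "8mer", 500), (0, "7mer-A1", 3200), (1, "7mer-m8", 1500),
                   (2, "6mer", 5200), (2, "8mer", 6100)]
        mirnas, region, _ = sim.emit_sequences(
            n_mirnas=5, utr_length=utr_len, planted_sites=planted, seed=config.seed
        )
        amps = default_amplicons(utr_len)
        io.write_fasta(mirnas, outdir / "mirnas.fa")
        io.write_fasta([region], outdir / "utr.fa")
        io.write_amplicons_bed(amps, outdir / "amplicons.bed", chrom=region.id)
        written.extend(["mirnas.fa", "utr.fa", "amplicons.bed"])

        sites = []
        for m in mirnas:
            sites.extend(seed_scan.assign_amplicons(seed_scan.scan_sites(m, region), amps))
        sites.sort(key=lambda s: (s.start, s.mirna_id))
        io.write_sites_bed(sites, outdir / "sites.bed")
        written.append("sites.bed")
        census = seed_scan.site_census(mirnas, [region], amps)
        emit(census.reset_index(), "site_census.tsv")
        return sites

    stage_seedscan()

    # -- stage: cohort -------------------------------------------------------
    @_stage("cohort")
    def stage_cohort():
        table, ctruth = sim.simulate_expression_cohort(
            n_per_group=config.cohort_n_per_group,
            mir30d_crpc_log2_shift=config.mir30d_crpc_log2_shift,
            coupling_strength=config.coupling_strength,
            seed=config.seed,
        )
        emit(table, "cohort.tsv")
        groups = expression_stats.sample_groups(table)
        levels, excluded = expression_stats.normalize_ddpcr(table)
        psa = expression_stats.relative_qpcr(table)
        comp = expression_stats.group_compare(levels, groups)
        emit(comp, "cohort_group_tests.tsv", {"excluded_samples": ",".join(excluded)})

        crpc = groups[groups == "CRPC"].index
        rows = []
        for analyte in levels.columns:
            for method in ("pearson", "spearman"):
                r, p, n = expression_stats.correlate(
                    levels.loc[levels.index.intersection(crpc), analyte],
                    psa.loc[psa.index.intersection(crpc)],
                    method=method,
                )
                rows.append(
                    {"analyte": analyte, "method": method, "r": r, "p_value": p, "n": n}
                )
        emit(pd.DataFrame(rows), "cohort_psa_correlations.tsv")

        two_groups = groups[groups.isin(["normal", "CRPC"])]
        expr = levels.dropna().T
        expr = expr.loc[:, expr.columns.intersection(two_groups.index)]
        de = expression_stats.de_filter(
            expr,
            two_groups,
            reference_group="normal",
            fdr_alpha=config.fdr_alpha,
            min_fc=config.min_fc,
        )
        emit(de.reset_index().rename(columns={"index": "analyte"}), "cohort_de_filter.tsv")

    stage_cohort()

    params = {k: v for k, v in asdict(config).items() if k != "outdir"}
    manifest = io.write_manifest(outdir, written, params)
    written.append("manifest.json")
    return manifest
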