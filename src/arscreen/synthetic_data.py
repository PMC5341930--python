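"""Planted-truth simulators for every pipeline input.

One 810-mimic library is screened in four assays: AR protein and PSA protein
by lysate microarray (LMA) across three cell lines, AR transcriptional
activity by dual-luciferase reporter, and viable cell density by secreted
Metridia luciferase — all in LNCaP-derived lines.  The generator emulates the
qualitative behaviour of such screens: a globally, mildly suppressive mimic
library; a minority of strong AR-axis suppressors acting coherently across
assays and cell lines; 3-step lysate dilution series (1, 1:4, 1:16) with a
detector ceiling that pushes the most concentrated dilution out of the linear
range; multiplicative triplicate spot noise; and occasional
background-oversubtracted (negative) intensities.

Effect model (log2 scale).  Every mimic carries a shared "AR-axis" effect

    s_i = global_shift + hit_i * (suppressor_effect - global_shift)
          + shared_effect_sd * z_i

and each (assay, cell line) observes ``s_i`` plus independent latent noise of
standard deviation ``cell_effect_sd``.  The between-assay correlation of
recovered log2 fold changes is therefore a derived quantity; when
``cell_effect_sd`` is not given it is solved in closed form from the target
``inter_assay_rho``::

    V_hit      = p (1 - p) (suppressor_effect - global_shift)^2,  p = k / n
    V_shared   = V_hit + shared_effect_sd^2
    v_measure  = 2 * 0.4487 * ln(1 + spot_cv^2) / ln(2)^2      (LMA, see note)
    cell_var   = V_shared * (1 - rho) / rho - v_measure        (clipped >= 0)

``v_measure`` is the analytic log2 variance contributed by taking the median
of three lognormal spot replicates in each of two channels (0.4487 is the
variance of the median of three iid standard normals).  With
``inter_assay_rho = 0`` the shared axis must be switched off
(``shared_effect_sd = 0``) and ``cell_effect_sd`` supplied explicitly; all
screens are then mutually independent — the null-calibration condition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ASSAYS = ("AR_protein", "PSA_protein", "AR_activity", "viability")
SPOT_COLUMNS = (
    "slide_id",
    "cell_line",
    "mimic_id",
    "channel",
    "dilution_factor",
    "replicate",
    "intensity",
)
PLATE_COLUMNS = ("plate_id", "well", "mimic_id", "assay", "replicate", "luminescence")
COHORT_COLUMNS = ("sample_id", "group", "analyte", "measure_type", "value")

CONTROL_LYSATES = ("PC3", "DU145")  # AR/PSA-negative control cell lysates
CONTROL_SIRNA = "ctrl-siRNA"
AR_SIRNA = "AR-siRNA"

#: variance of the median of three iid standard normal variates
_MEDIAN3_VAR = 0.4487

# fixed RNG stream offsets so each simulated artefact has its own substream
_STREAM_TRUTH = 0
_STREAM_LMA = {"AR": 1, "PSA": 2}
_STREAM_REPORTER = 3
_STREAM_VIABILITY = 4
_STREAM_COHORT = 5
_STREAM_SEQ = 6


@dataclass
class ScreenSimConfig:
    """Conditions of the simulated 810-mimic screen.

    ``suppressor_effect`` and ``global_shift`` are mean log2 fold changes of
    planted hits and null mimics; ``dilution_factors`` are the nominal lysate
    dilutions, most concentrated first; ``saturation_level`` is the hard
    detector ceiling in fluorescence units.
    """

    n_mimics: int = 810
    cell_lines: tuple[str, ...] = ("LNCaP", "VCaP", "LAPC4")
    activity_cell_line: str = "LNCaP"
    n_true_suppressors: int = 40
    suppressor_effect: float = -2.0
    global_shift: float = -0.2
    inter_assay_rho: float = 0.45
    shared_effect_sd: float = 0.05
    cell_effect_sd: float | None = None
    spot_cv: float = 0.15
    dilution_factors: tuple[float, ...] = (1.0, 0.25, 0.0625)
    saturation_level: float = 45000.0
    base_intensity: float = 55000.0
    negative_fraction: float = 0.01
    n_controls: int = 8
    n_replicates: int = 3
    ar_sirna_effect: float = -3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_true_suppressors < self.n_mimics:
            raise ValueError("n_true_suppressors must be < n_mimics")
        d = tuple(self.dilution_factors)
        if any(not 0 < x <= 1 for x in d) or any(
            a <= b for a, b in zip(d, d[1:])
        ):
            raise ValueError("dilution_factors must be strictly decreasing in (0, 1]")
        if self.spot_cv < 0:
            raise ValueError("spot_cv must be >= 0")
        if self.saturation_level <= 0:
            raise ValueError("saturation_level must be > 0")
        if not 0 <= self.negative_fraction < 1:
            raise ValueError("negative_fraction must be in [0, 1)")
        if not 0 <= self.inter_assay_rho < 1:
            raise ValueError("inter_assay_rho must be in [0, 1)")
        if self.inter_assay_rho == 0 and (
            self.shared_effect_sd != 0 or self.cell_effect_sd is None
        ):
            raise ValueError(
                "inter_assay_rho=0 requires shared_effect_sd=0 and an explicit "
                "cell_effect_sd (fully independent screens)"
            )
        if self.activity_cell_line not in self.cell_lines:
            raise ValueError("activity_cell_line must be one of cell_lines")

    # -- closed-form calibration -------------------------------------------
    @property
    def lma_measurement_var(self) -> float:
        """Approximate log2 variance of a recovered LMA log fold change."""
        sigma_log2_sq = math.log1p(self.spot_cv**2) / math.log(2) ** 2
        return 2.0 * _MEDIAN3_VAR * sigma_log2_sq

    @property
    def hit_variance(self) -> float:
        p = self.n_true_suppressors / self.n_mimics
        return p * (1 - p) * (self.suppressor_effect - self.global_shift) ** 2

    def resolved_cell_effect_sd(self) -> float:
        if self.cell_effect_sd is not None:
            return self.cell_effect_sd
        shared = self.hit_variance + self.shared_effect_sd**2
        rho = self.inter_assay_rho
        var = shared * (1 - rho) / rho - self.lma_measurement_var
        return math.sqrt(max(var, 1e-4))

    def mimic_ids(self) -> list[str]:
        return [f"mimic_{i:04d}" for i in range(1, self.n_mimics + 1)]

    def control_mimic_ids(self) -> list[str]:
        return [f"control_{i:02d}" for i in range(1, self.n_controls + 1)]


def null_independent_config(seed: int = 0, **overrides) -> ScreenSimConfig:
    """Config with no planted hits and mutually independent screens."""
    kw = dict(
        n_true_suppressors=0,
        inter_assay_rho=0.0,
        shared_effect_sd=0.0,
        cell_effect_sd=0.35,
        negative_fraction=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return ScreenSimConfig(**kw)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every simulated dataset.

    ``effects`` maps (assay, cell_line) -> per-mimic latent log2 effect
    (pandas Series indexed by mimic_id).  Cohort simulations fill
    ``sample_latent`` (per-sample latent AR activity) instead.
    """

    seed: int
    true_suppressors: list[str] = field(default_factory=list)
    effects: dict = field(default_factory=dict)
    negative_mimics: dict = field(default_factory=dict)
    sample_latent: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "true_suppressors": list(self.true_suppressors),
            "effects": {
                f"{assay}|{cell}": dict(zip(s.index, map(float, s.to_numpy())))
                for (assay, cell), s in self.effects.items()
            },
            "negative_mimics": {k: list(v) for k, v in self.negative_mimics.items()},
            "sample_latent": (
                None
                if self.sample_latent is None
                else dict(
                    zip(self.sample_latent.index, map(float, self.sample_latent))
                )
            ),
            "params": self.params,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _tnorm(rng: np.random.Generator, size) -> np.ndarray:
    """Standard normal draws truncated (clipped) at +/- 3 sd."""
    return np.clip(rng.standard_normal(size), -3.0, 3.0)


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def make_planted_truth(config: ScreenSimConfig) -> PlantedTruth:
    """Latent per-mimic effects for all assays/cell lines; seed-reproducible."""
    rng = _rng(config.seed, _STREAM_TRUTH)
    ids = config.mimic_ids()
    n = config.n_mimics
    hit_idx = (
        np.sort(rng.choice(n, size=config.n_true_suppressors, replace=False))
        if config.n_true_suppressors
        else np.array([], dtype=int)
    )
    is_hit = np.zeros(n, bool)
    is_hit[hit_idx] = True
    base = np.where(is_hit, config.suppressor_effect, config.global_shift)
    # latent z draws are bounded at 3 sd: screen log fold changes live in a
    # bounded range, and this keeps the sub-saturation dilutions within the
    # detector's linear range for every mimic
    shared = base + config.shared_effect_sd * _tnorm(rng, n)
    cell_sd = config.resolved_cell_effect_sd()

    effects: dict = {}
    for assay in ASSAYS:
        cells = (
            config.cell_lines
            if assay in ("AR_protein", "PSA_protein")
            else (config.activity_cell_line,)
        )
        for cell in cells:
            e = shared + cell_sd * _tnorm(rng, n)
            effects[(assay, cell)] = pd.Series(e, index=ids, name="log2_effect")
    return PlantedTruth(
        seed=config.seed,
        true_suppressors=[ids[i] for i in hit_idx],
        effects=effects,
        params=asdict(config),
    )


# ---------------------------------------------------------------------------
# LMA screens
# ---------------------------------------------------------------------------

def simulate_lma_screen(
    config: ScreenSimConfig, channel: str
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Simulate spot-level LMA tables for one target channel ("AR" or "PSA").

    Returns one SpotTable DataFrame per cell line (columns
    ``SPOT_COLUMNS``), each holding target-channel and GAPDH spots for every
    library mimic, control mimic, and the PC3/DU145 negative-control lysates,
    at every dilution in triplicate; plus the planted truth shared by all
    screens of this config.  A ``negative_fraction`` of library mimics per
    slide receives background-oversubtracted (negative) target intensities.
    """
    if channel not in ("AR", "PSA"):
        raise ValueError(f"channel must be 'AR' or 'PSA', got {channel!r}")
    assay = "AR_protein" if channel == "AR" else "PSA_protein"
    truth = make_planted_truth(config)
    channel_scale = 1.0
    background_frac = 0.03  # control-lysate target signal, proportional to lysate

    tables: dict[str, pd.DataFrame] = {}
    for ci, cell in enumerate(config.cell_lines):
        rng = _rng(config.seed, _STREAM_LMA[channel], ci)
        effects = truth.effects[(assay, cell)]
        sample_ids = (
            list(effects.index)
            + config.control_mimic_ids()
            + list(CONTROL_LYSATES)
        )
        e = np.concatenate(
            [
                effects.to_numpy(),
                np.zeros(config.n_controls),  # control mimics: no effect
                np.zeros(2),  # placeholder for control lysates
            ]
        )
        is_lysate = np.zeros(len(sample_ids), bool)
        is_lysate[-2:] = True

        n_s, n_d, n_r = len(sample_ids), len(config.dilution_factors), 3
        dil = np.asarray(config.dilution_factors)
        shape = (n_s, n_d, n_r)
        gapdh = (
            config.base_intensity
            * dil[None, :, None]
            * _lognormal(rng, config.spot_cv, shape)
        )
        target_level = np.where(
            is_lysate, background_frac, channel_scale * 2.0 ** e
        )
        target = (
            config.base_intensity
            * target_level[:, None, None]
            * dil[None, :, None]
            * _lognormal(rng, config.spot_cv, shape)
        )
        gapdh = np.minimum(gapdh, config.saturation_level)
        target = np.minimum(target, config.saturation_level)

        # background over-subtraction: negative target intensities for a few mimics
        n_neg = int(round(config.negative_fraction * config.n_mimics))
        neg_ids: list[str] = []
        if n_neg:
            neg_pos = np.sort(rng.choice(config.n_mimics, size=n_neg, replace=False))
            target[neg_pos] = -rng.uniform(1.0, 50.0, size=(n_neg, n_d, n_r))
            neg_ids = [sample_ids[i] for i in neg_pos]
        truth.negative_mimics[f"{cell}|{channel}"] = neg_ids

        slide = f"{cell}_{channel}"
        frames = []
        for ch_name, inten in ((channel, target), ("GAPDH", gapdh)):
            frames.append(
                pd.DataFrame(
                    {
                        "slide_id": slide,
                        "cell_line": cell,
                        "mimic_id": np.repeat(sample_ids, n_d * n_r),
                        "channel": ch_name,
                        "dilution_factor": np.tile(np.repeat(dil, n_r), n_s),
                        "replicate": np.tile(np.arange(1, n_r + 1), n_s * n_d),
                        "intensity": inten.ravel(),
                    }
                )
            )
        tables[cell] = pd.concat(frames, ignore_index=True)
    return tables, truth


# ---------------------------------------------------------------------------
# plate-based screens
# ---------------------------------------------------------------------------

def _plate_rows(
    plate_id: str,
    sample_ids: list[str],
    assays: dict[str, np.ndarray],
    n_rep: int,
) -> pd.DataFrame:
    frames = []
    wells = [f"W{i + 1:04d}_{r + 1}" for i in range(len(sample_ids)) for r in range(n_rep)]
    for assay, lum in assays.items():
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well": wells,
                    "mimic_id": np.repeat(sample_ids, n_rep),
                    "assay": assay,
                    "replicate": np.tile(np.arange(1, n_rep + 1), len(sample_ids)),
                    "luminescence": lum.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_reporter_screen(
    config: ScreenSimConfig,
    n_replicates: int | None = None,
    measurement_seed: int | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Dual-luciferase AR-activity screen: firefly coupled to the mimic's
    AR-activity effect, Renilla independent; triplicate wells per mimic plus
    control-siRNA and AR-siRNA reference wells.

    ``measurement_seed`` redraws only the well noise while keeping the
    planted truth of ``config.seed`` — an independent biological replicate of
    the same library (used for verification experiments).
    """
    n_rep = n_replicates if n_replicates is not None else max(config.n_replicates, 3)
    truth = make_planted_truth(config)
    noise_seed = config.seed if measurement_seed is None else measurement_seed
    rng = _rng(noise_seed, _STREAM_REPORTER)
    effects = truth.effects[("AR_activity", config.activity_cell_line)]
    sample_ids = (
        list(effects.index)
        + config.control_mimic_ids()
        + [CONTROL_SIRNA, AR_SIRNA]
    )
    e = np.concatenate(
        [
            effects.to_numpy(),
            np.zeros(config.n_controls + 1),
            [config.ar_sirna_effect],
        ]
    )
    shape = (len(sample_ids), n_rep)
    firefly = 5.0e5 * (2.0 ** e)[:, None] * _lognormal(rng, config.spot_cv, shape)
    renilla = 2.0e5 * _lognormal(rng, config.spot_cv, shape)
    table = _plate_rows(
        "reporter_plate",
        sample_ids,
        {"reporter_firefly": firefly, "reporter_renilla": renilla},
        n_rep,
    )
    return table, truth


def simulate_viability_screen(
    config: ScreenSimConfig, n_replicates: int = 4
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Secreted-MLuc viability screen, quadruplicate single-channel wells."""
    truth = make_planted_truth(config)
    rng = _rng(config.seed, _STREAM_VIABILITY)
    effects = truth.effects[("viability", config.activity_cell_line)]
    sample_ids = (
        list(effects.index)
        + config.control_mimic_ids()
        + [CONTROL_SIRNA, AR_SIRNA]
    )
    e = np.concatenate(
        [
            effects.to_numpy(),
            np.zeros(config.n_controls + 1),
            [config.ar_sirna_effect],
        ]
    )
    shape = (len(sample_ids), n_replicates)
    mluc = 1.0e5 * (2.0 ** e)[:, None] * _lognormal(rng, config.spot_cv, shape)
    table = _plate_rows("viability_plate", sample_ids, {"mluc": mluc}, n_replicates)
    return table, truth


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

MIR30_ANALYTES = ("miR-30a-5p", "miR-30b-3p", "miR-30c-5p", "miR-30d-5p")

#: planted mean log2 shifts of miR-30 members vs normal prostate; miR-30d's
#: CRPC entry is overridden by the ``mir30d_crpc_log2_shift`` argument
_GROUP_SHIFTS = {
    "miR-30a-5p": {"primary": 0.0, "CRPC": -0.2},
    "miR-30b-3p": {"primary": -0.2, "CRPC": -0.3},
    "miR-30c-5p": {"primary": -0.3, "CRPC": -0.7},
    "miR-30d-5p": {"primary": -0.5, "CRPC": -1.0},
}
_LATENT_GROUP_MEAN = {"normal": 0.0, "primary": 0.5, "CRPC": 1.0}
_REL_BASE = {  # relative abundance of each miRNA vs RNU6B at baseline
    "miR-30a-5p": 0.08,
    "miR-30b-3p": 0.02,
    "miR-30c-5p": 0.05,
    "miR-30d-5p": 0.04,
}


def simulate_expression_cohort(
    n_per_group: int = 15,
    mir30d_crpc_log2_shift: float = -1.0,
    coupling_strength: float = -0.6,
    seed: int = 0,
    noise: bool = True,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Three-group tissue cohort (normal / primary PCa / metastatic CRPC).

    Emits a long-format cohort table: ddPCR copy counts for the four miR-30
    members plus RNU6B, and qPCR Ct for PSA and beta-actin (ACTB).  A latent
    per-sample AR-activity variable raises PSA everywhere; inside the CRPC
    group the miR-30d-5p level is coupled to that latent variable with
    correlation ``coupling_strength`` (negative = inverse), producing an
    inverse miR-30d/PSA correlation across CRPC samples.  ``noise=False``
    silences every stochastic term (expectation-level output).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not -1.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must be in [-1, 1]")
    rng = _rng(seed, _STREAM_COHORT)
    latent_sd = 0.8 if noise else 0.0
    mir_sd = 0.6 if noise else 0.0
    ct_sd = 0.15 if noise else 0.0
    sample_cv = 0.3 if noise else 0.0

    groups = ["normal"] * n_per_group + ["primary"] * n_per_group + ["CRPC"] * n_per_group
    prefixes = {"normal": "N", "primary": "P", "CRPC": "C"}
    counts: dict[str, int] = {}
    sample_ids = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        sample_ids.append(f"{prefixes[g]}{counts[g]:02d}")
    n = len(sample_ids)
    grp = np.asarray(groups)

    z_latent = rng.standard_normal(n)
    latent = np.array([_LATENT_GROUP_MEAN[g] for g in groups]) + latent_sd * z_latent

    # miRNA log2 relative levels (vs RNU6B), per analyte
    shifts = {a: dict(v) for a, v in _GROUP_SHIFTS.items()}
    shifts["miR-30d-5p"]["CRPC"] = mir30d_crpc_log2_shift
    mir_log2 = {}
    for analyte in MIR30_ANALYTES:
        shift = np.array([shifts[analyte].get(g, 0.0) for g in groups])
        eps = rng.standard_normal(n)
        level = shift + mir_sd * eps
        if analyte == "miR-30d-5p" and coupling_strength != 0.0:
            # inside CRPC, replace the independent spread by one correlated
            # with the latent AR axis at the requested strength
            crpc = grp == "CRPC"
            coupled = coupling_strength * z_latent + math.sqrt(
                1 - coupling_strength**2
            ) * rng.standard_normal(n)
            level = np.where(crpc, shift + mir_sd * coupled, level)
        mir_log2[analyte] = level

    # ddPCR measurement: RNU6B reference copies, then Poisson counting
    rnu6b = 20000.0 * _lognormal(rng, sample_cv, n)
    rows = []
    for analyte in MIR30_ANALYTES:
        lam = rnu6b * _REL_BASE[analyte] * 2.0 ** mir_log2[analyte]
        copies = rng.poisson(lam).astype(float) if noise else lam
        rows.append((analyte, "ddpcr_copies", copies))
    rnu6b_obs = rng.poisson(rnu6b).astype(float) if noise else rnu6b
    rows.append(("RNU6B", "ddpcr_copies", rnu6b_obs))

    # qPCR: PSA Ct tracks the latent AR axis (1 latent unit ~ 1 cycle)
    psa_log2_rq = -2.0 + 1.0 * latent
    actb_ct = 18.0 + ct_sd * rng.standard_normal(n)
    psa_ct = actb_ct - psa_log2_rq + ct_sd * rng.standard_normal(n)
    rows.append(("ACTB", "qpcr_ct", actb_ct))
    rows.append(("PSA", "qpcr_ct", psa_ct))

    frames = [
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "analyte": analyte,
                "measure_type": mtype,
                "value": values,
            }
        )
        for analyte, mtype, values in rows
    ]
    table = pd.concat(frames, ignore_index=True)
    truth = PlantedTruth(
        seed=seed,
        sample_latent=pd.Series(latent, index=sample_ids, name="latent_ar_activity"),
        params={
            "n_per_group": n_per_group,
            "mir30d_crpc_log2_shift": mir30d_crpc_log2_shift,
            "coupling_strength": coupling_strength,
            "noise": noise,
            "group_shifts": shifts,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------

def emit_sequences(
    n_mirnas: int,
    utr_length: int,
    planted_sites: list[tuple[int, str, int]],
    seed: int = 0,
    region_id: str = "synthetic_UTR",
    role: str = "UTR3",
):
    """Random miRNAs and a background region carrying exactly the planted sites.

    ``planted_sites`` is a list of (mirna_index, site_type, start) with start
    1-based on the region; planted spans must not overlap and must leave one
    flanking base on each side.  The background is rejection-sampled so that
    the planted miRNAs have no canonical site anywhere else (and planted-site
    flanks are chosen so a site's type is not accidentally upgraded).

    Returns ``(mirnas, region, truth_sites)`` where ``truth_sites`` lists the
    planted sites as :class:`~arscreen.seed_scan.SeedSite` objects.
    """
    from . import seed_scan as ss

    rng = _rng(seed, _STREAM_SEQ)
    span_len = {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    mirnas = [
        ss.MatureMiRNA(
            id=f"mir_syn_{i + 1:02d}",
            sequence="".join(rng.choice(list("ACGU"), size=22)),
        )
        for i in range(n_mirnas)
    ]

    spans = []
    for mi, stype, start in planted_sites:
        if stype not in span_len:
            raise ValueError(f"unknown site type {stype!r}")
        end = start + span_len[stype] - 1
        if start < 2 or end > utr_length - 1:
            raise ValueError(
                f"planted site at {start} must leave a flanking base on each side"
            )
        spans.append((mi, stype, start, end))
    ordered = sorted(spans, key=lambda x: x[2])
    for (_, _, _, e1), (_, _, s2, _) in zip(ordered, ordered[1:]):
        if e1 + 2 >= s2:
            raise ValueError("planted sites (with flanks) must not overlap")

    planted_idx = sorted({mi for mi, *_ in spans})
    cores = {mi: ss.seed_match_core(mirnas[mi]) for mi in planted_idx}
    for _ in range(50):
        seq = list(rng.choice(list("ACGT"), size=utr_length))
        protected: set[int] = set()
        # write planted site spans and pin their flanks
        for mi, stype, start, end in spans:
            p8 = comp[mirnas[mi].sequence[7].replace("U", "T")]
            if stype == "8mer":
                site = p8 + cores[mi] + "A"
            elif stype == "7mer-m8":
                site = p8 + cores[mi]
            elif stype == "7mer-A1":
                site = cores[mi] + "A"
            else:
                site = cores[mi]
            seq[start - 1 : end] = list(site)
            # flanks must not upgrade the type or extend the match
            left, right = start - 2, end
            if stype in ("7mer-A1", "6mer") and seq[left] == p8:
                seq[left] = rng.choice([b for b in "ACGT" if b != p8])
            if stype in ("7mer-m8", "6mer") and seq[right] == "A":
                seq[right] = rng.choice(["C", "G", "T"])
            protected.update(range(left, right + 1))
        planted_anchors = {
            (mi, start - 1 + (1 if stype in ("8mer", "7mer-m8") else 0))
            for mi, stype, start, end in spans
        }

        # scrub accidental core matches of the planted miRNAs
        stuck = False
        for _ in range(2000):
            dirty = False
            s = "".join(seq)
            for mi in planted_idx:
                pos = s.find(cores[mi])
                while pos != -1:
                    if (mi, pos) not in planted_anchors:
                        free = [
                            j for j in range(pos, pos + 6) if j not in protected
                        ]
                        if not free:
                            stuck = True
                            break
                        j = int(rng.choice(free))
                        seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
                        dirty = True
                        break
                    pos = s.find(cores[mi], pos + 1)
                if stuck or dirty:
                    break
            if stuck or not dirty:
                break
        if stuck:
            continue

        region = ss.TranscriptRegion(id=region_id, sequence="".join(seq), role=role)
        truth_sites = []
        clean = True
        for mi in planted_idx:
            found = ss.scan_sites(mirnas[mi], region)
            want = sorted((s, e, t) for mj, t, s, e in spans if mj == mi)
            got = sorted((s.start, s.end, s.site_type) for s in found)
            if got != want:
                clean = False
                break
            truth_sites.extend(found)
        if clean:
            truth_sites.sort(key=lambda s: (s.start, s.mirna_id))
            return mirnas, region, truth_sites
    raise RuntimeError("could not rejection-sample a clean background region")
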