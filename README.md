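# arscreen

Analysis pipeline for functional miRNA-mimic screens targeting the androgen
receptor (AR) signaling axis in prostate cancer, exercised end-to-end on
synthetic data with planted ground truth.

High-throughput mimic libraries (here: 810 miRNA mimics, three AR-positive
cell lines) are screened in four complementary assays — AR protein and PSA
protein by lysate microarray (LMA), AR transcriptional activity by
dual-luciferase reporter, and viable cell density by secreted *Metridia*
luciferase. Turning those raw readouts into a credible candidate list
requires a chain of quantification and selection rules: linear-range
dilution selection, triplicate aggregation, GAPDH/Renilla normalization,
fold change vs negative-control mimics, a cross-assay top-quartile consensus
rule, one-sided verification statistics, miRNA seed-site mapping in the AR
3'UTR and coding region, and cohort-level expression statistics (ddPCR/qPCR
normalization, group tests, correlation, BH-FDR filtering). `arscreen`
implements that chain as a reusable, tested library for screen analysts, and
ships a planted-truth simulator so every stage is verifiable without access
to raw screen data.

## The core quantities

* **LMA fold change** per mimic *i*, at the one dilution within the linear
  range: `FC_i = (target_i / GAPDH_i) / mean_c (target_c / GAPDH_c)` over
  control mimics *c* on the same slide, reported with `log2 FC`; mimics with
  negative raw values are removed.
* **Consensus rule**: with `top(S)` the 25% most-suppressive mimics of screen
  *S*, the candidate core is
  `top(activity) ∩ {AR-protein top in >=2 cell lines} ∩ {PSA-protein top in >=2 cell lines}`,
  plus the 5 most potent activity inhibitors not already selected.
* **Verification**: one-sided Welch t-test (candidate < control) on log
  normalized luminescence; verified ⇔ mean relative activity < 1 and
  p < 0.05.
* **Seed sites**: canonical 8mer / 7mer-m8 / 7mer-A1 / 6mer matches to the
  reverse complement of miRNA positions 2-7(8), strongest type per locus.
* **Expression filter**: BH-FDR q < 0.05 and linear |FC| > 1.2 on two-sided
  Welch tests of log2 levels.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data; each stage reads the previous stage's TSV outputs under `results/`.

```sh
python analysis/01_simulate_screens.py --seed 1
python analysis/02_quantify_lma.py
python analysis/03_normalize_plate_assays.py
python analysis/04_select_candidates.py
python analysis/05_verify_candidates.py --seed 1
python analysis/06_scan_seed_sites.py --seed 1
python analysis/07_cohort_expression.py
```

At seed 1 the screens quantify to (script 02/03 output, abridged):

```
AR_protein   LNCaP : dilution 0.25, 65% of mimics below control, 8 removed (negative values)
PSA_protein  LNCaP : dilution 0.25, 70% of mimics below control, 8 removed (negative values)
AR activity: 67% of mimics below control; AR-siRNA control fc = 0.120
viability:   71% of mimics below control
```

— the 1:1 dilution is discarded by the saturation guard, the library is
broadly mildly suppressive, and the positive-control AR siRNA lands at 12%
of control activity. Consensus selection (script 04) then reports:

```
core candidates: 46; extras: 5
AR vs PSA protein log2 FC, LNCaP: Pearson r = 0.442 (p = 3.2e-39, n = 794)
vs planted truth: precision 0.87, recall 1.00
```

All 40 planted suppressors are recovered (recall 1.00) alongside a handful of
chance-level co-occurrences — close to the ~5 expected from the independence
calculation. The cohort stage (script 07) recovers the planted miR-30
biology:

```
miR-30c-5p  CRPC     ratio vs normal = 0.64  p = 0.0138 *
miR-30d-5p  primary  ratio vs normal = 0.67  p = 0.00313 *
miR-30d-5p  CRPC     ratio vs normal = 0.54  p = 6.85e-05 *
miR-30d-5p vs PSA mRNA in CRPC: Pearson r = -0.316 (p = 0.252, n = 15)
DE filter (FDR < 0.05, |FC| > 1.2), CRPC vs normal: 2 of 4 miR-30 members pass
```

miR-30d-5p is significantly reduced in both tumour groups; at the default
moderate latent coupling (-0.6) the inverse miR-30d/PSA correlation is
present but, at n = 15, not always individually significant — the
calibration studies below quantify exactly how often it is.

Everything is also runnable in one call:

```python
from arscreen.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(outdir="results/run", seed=1))
```

which writes every intermediate table plus a checksummed `manifest.json`;
rerunning with the same seed reproduces the manifest byte-for-byte.

## Layout

```
src/arscreen/      library: synthetic_data, lma_quant, assay_norm, consensus,
                   seed_scan, expression_stats, io, pipeline, benchmarks
analysis/          numbered narrative drivers (01..07) writing under results/
tests/             pytest suite incl. end-to-end property checks
scripts/           acceptance.py (property-study runner)
docs/methods.md    models, rules, calibration rationale, limitations
```
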