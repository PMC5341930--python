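# Methods

`arscreen` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the analysis chain of a four-assay functional
miRNA-mimic screen for regulators of the androgen receptor (AR): lysate
microarray (LMA) quantification of AR and PSA protein, dual-luciferase AR
transcriptional activity, secreted-luciferase (MLuc) cell viability,
cross-assay consensus hit calling, canonical seed-site mapping in the AR
3'UTR/CDS with site-ablating mutagenesis, and a three-group tissue-cohort
expression analysis (ddPCR miR-30 quantification, qPCR PSA, group tests,
correlation, BH-FDR filtering).

The real screen's raw intensities and patient RNA are not published, so every
claim this package can make is a *property* of the analysis chain, checked on
simulations whose truth is known. This note documents the models, the
numerical rules, and the reasoning behind the open design choices.

## Screen simulator

### Latent effect model

Each of the 810 library mimics carries a log2-scale effect per assay and cell
line, built from three components:

```
shared_i      = global_shift + hit_i * (suppressor_effect - global_shift)
                + shared_effect_sd * z_i
effect_i(a,c) = shared_i + cell_effect_sd * z_i(a,c)
```

* `hit_i` marks the `n_true_suppressors` (default 40) planted AR-axis
  suppressors; `suppressor_effect` (default -2.0 log2) is their mean effect
  in every assay and cell line — planted hits act coherently, which is what
  the consensus rule exploits.
* `global_shift` (default -0.2 log2) models the broad, mild suppressiveness
  of mimic libraries: the majority of mimics land below the control line
  (observed 60-75% per screen at defaults) without being specific hits.
* `shared_effect_sd` (default 0.05) is the spread of *real but weak* shared
  AR-axis activity among non-hit mimics. It is deliberately small: the
  top-25% / >=2-cell-line consensus rule is designed so that non-replicating
  mimics fail it, and the package's planted-recovery contract (core precision
  and recall >= 0.9 with 40 hits) is only attainable when null mimics do not
  co-rank strongly across screens — the ~5 chance-level core members implied
  by the independence calculation already consume half the false-positive
  budget.
* All z draws are standard normal clipped at +/-3: screen log fold changes
  are bounded in practice, and the bound keeps every sub-saturation dilution
  of the simulated slides inside the detector's linear range, so the
  noise-free quantification chain inverts exactly.

### Inter-assay correlation is derived, not set

The between-assay Pearson correlation of recovered log2 fold changes (the
screen's AR-vs-PSA cross-check) is a derived quantity. Writing
`p = n_hits/n`, `delta = suppressor_effect - global_shift`, the shared
variance is

```
V_shared = p(1-p) delta^2 + shared_effect_sd^2
```

and `cell_effect_sd`, when not given explicitly, is solved from the target
`inter_assay_rho`:

```
cell_var = V_shared * (1 - rho) / rho  -  v_measure,   clipped >= 1e-4
```

where `v_measure = 2 * 0.4487 * ln(1 + spot_cv^2) / ln(2)^2` is the analytic
log2 variance a recovered LMA fold change inherits from measurement: median
of three lognormal spot replicates (0.4487 = variance of the median of three
iid standard normals) in each of two channels. At defaults the calibration
lands the observed correlation within ~0.03 of the requested rho at n = 810.
With `inter_assay_rho = 0` the shared axis must be switched off and
`cell_effect_sd` supplied explicitly; all screens are then mutually
independent (`null_independent_config`), the condition under which the
closed-form null expectation for the consensus core applies.

### Intensity model

Spot intensity is `base_intensity * dilution * 2^effect * lognormal(cv)`
(GAPDH channel without the effect term), hard-clipped at
`saturation_level`. Defaults put `base_intensity` (55 000) *above* the
ceiling (45 000), so the 1:1 dilution genuinely leaves the linear range —
selecting a quantifiable dilution is a real decision, as on physical slides —
while the 1:4 step stays clip-free for every mimic (guaranteed by the +/-3 sd
effect bound). Each slide carries the library, 8 negative-control mimic
lysates (effect 0), and PC3/DU145 AR/PSA-negative control lysates whose
target-channel signal is a small background proportional to spotted lysate
(3% of GAPDH level) — proportionality is what makes these lysates usable for
dilution-linearity checks. A configurable 1% of mimics per slide receives
negative (background-oversubtracted) target intensities to exercise the
removal rule. Plate screens (reporter, viability) use the same multiplicative
noise on wells; the reporter couples firefly, not Renilla, to the mimic's
AR-activity effect, and AR-siRNA wells carry a fixed -3 log2 effect.
`simulate_reporter_screen(measurement_seed=...)` redraws well noise while
keeping the planted truth — an independent biological replicate of the same
library, used for verification.

### Cohort simulator

45 samples (normal prostate, primary PCa, metastatic CRPC; 15 each). A
latent per-sample AR-activity variable (group means 0 / 0.5 / 1.0, sd 0.8)
drives PSA: `log2 RQ = -2 + latent`, measured as qPCR Ct vs beta-actin with
Ct noise sd 0.15. miR-30 members carry planted group shifts vs normal
(log2): miR-30a -0.2 (CRPC), miR-30b -0.2/-0.3, miR-30c -0.3/-0.7,
miR-30d -0.5/-1.0 (primary/CRPC; the miR-30d CRPC shift is the
`mir30d_crpc_log2_shift` argument), with biological spread sd 0.6. Inside
the CRPC group only, the miR-30d spread is replaced by a component correlated
with the latent AR axis at `coupling_strength` (default -0.6), producing the
inverse miR-30d/PSA correlation across CRPC samples; the other members are
left uncoupled (their planted shifts alone produce the weaker inverse trends).
ddPCR measurement is Poisson counting around `RNU6B_copies * rel_base *
2^level` with RNU6B at ~20 000 copies and 30% sample-to-sample spread.
`noise=False` silences every stochastic term and yields expectation-level
output (used by exactness tests).

Note on the null: at n = 15 the sampling sd of a null Pearson r is ~0.27, so
even a perfectly uncoupled simulation produces |r| >= 0.3 in roughly a
quarter of cohorts; the null test asserts agreement with the exact t-based
null distribution of r, not an ad-hoc band.

### Sequence fixtures

`emit_sequences` builds random 22-nt miRNAs and a random DNA region carrying
*exactly* the requested canonical sites: planted site spans are written
literally, their flanking bases are pinned so a site's type cannot be
silently upgraded (no accidental A1 adenine or position-8 partner), and
accidental seed-core occurrences of the planted miRNAs elsewhere are scrubbed
by re-randomizing one free base at a time until a full scan confirms the
planted truth and nothing else.

## Quantification rules

* **Linear-range dilution** (per slide and channel): dilutions whose
  slide-wide median intensity reaches 90% of the slide's maximum observed
  intensity are discarded (a median at the ceiling is the signature of bulk
  clipping; an unclipped heterogeneous slide keeps its median well below its
  maximum). Among the rest, the dilution maximizing the through-origin R^2 of
  median control-lysate intensity vs nominal dilution factor — over that
  dilution and all more-dilute usable steps — wins; a single-point series
  cannot demonstrate linearity and scores -inf; ties go to the more
  concentrated dilution. If only one dilution survives the guard it is
  returned; if none do, the slide is reported as saturated by name.
* **Replicate aggregation**: median of the <=3 spot replicates per channel
  (robust to one bad spot); replicate CV (sd/mean) > 0.25 on the target
  channel flags `high_cv` (retained, flagged).
* **Normalization**: `norm_signal = target / GAPDH` per mimic;
  `fc = norm_signal / mean(control-mimic norm_signal)` per slide (per-slide
  control normalization absorbs slide effects); `log2_fc = log2(fc)`. Mimics
  with a non-positive raw intensity in either channel are removed before
  division (the only reading under which the ratio is defined) and flagged.
  Ranks ascend by fc (most suppressive first), ties broken lexicographically
  by mimic id for reproducibility.
* **Reporter / viability**: per-well firefly/Renilla ratio (wells with
  non-positive Renilla dropped and flagged; mimics with no surviving wells
  removed), mean ratio per mimic, fold change vs the control-mimic mean;
  viability identically on single-channel MLuc wells.

## Consensus selection

Top fraction = the `floor(fraction * N_retained)` smallest-fc mimics of a
screen (retained mimics only; removed mimics are not in the denominator).
Core = top-quartile in the AR-activity screen AND top-quartile AR-protein in
>= 2 cell lines AND top-quartile PSA-protein in >= 2 cell lines, each protein
assay counting its cell lines independently (the alternative joint reading —
>= 2 cell lines where both protein assays pass together — is available as
`joint_cell_line_rule`). Extras = the `n_extra` (default 5) best AR-activity
ranks outside the core. Output order: core by AR-activity rank, then extras.
Under fully independent screens the expected core size is
`N * p_act * P(Bin(3, p) >= 2)^2` with per-screen membership probabilities
`floor(fraction*N)/N`; the null-calibration check compares simulation against
exactly this number.

## Statistics

* **Verification**: one-sided Welch t-test, candidate wells vs pooled control
  wells, alternative "candidate < control", computed on *log* normalized
  luminescence — the noise is multiplicative, and on the linear scale the
  small-sample one-sided test is measurably anti-conservative (~0.08 at
  alpha = 0.05 with 6 wells) while the log scale is near-nominal (~0.055).
  Reported mean relative activity and SE stay linear; verified means
  mean < 1 and p < 0.05, with no multiple-testing correction (raw-p rule,
  stated in the output metadata). Zero variance in both groups with equal
  means yields p = 1.
* **Cohort group tests**: two-sided Welch on log2 normalized levels vs the
  normal-prostate group; ratios reported as ratios of geometric means.
  Samples whose reference gene (RNU6B) fails are excluded pairwise.
* **Correlation**: Pearson (t approximation) and Spearman (exact for small n
  via scipy) both computed for the miR-30/PSA analysis; neither is asserted
  as canonical.
* **Differential-expression filter**: per-feature two-sided Welch on log2
  values, Benjamini-Hochberg step-up q-values (statsmodels), pass =
  (q < 0.05) AND (linear |FC| > 1.2). q-values are verified against a
  brute-force step-up oracle.

## Seed-site scanning

Canonical TargetScan-style taxonomy (8mer, 7mer-m8, 7mer-A1, 6mer) on the
region's sense strand: a site is an exact match to the DNA reverse complement
of miRNA positions 2-7, extended by the partner of position 8 on the 5' side
and/or an A opposite position 1 on the 3' side. Each core locus is reported
once with the strongest applicable type; overlapping weaker sites of the same
miRNA are suppressed (stronger type first, then leftmost). U/T equivalence is
handled by mapping the miRNA to DNA before complementing; CDS regions use the
identical taxonomy. Internal coordinates are 1-based inclusive; BED exports
are 0-based half-open. The scanner is verified exactly against an independent
sliding-window enumeration on random inputs.

Amplicon assignment is by full containment of the site span, so sites in
overlap zones belong to multiple amplicons. The bundled AR1-AR7 fixture tiles
a synthetic 6.9 kb UTR with ~40% overlapping windows; real amplicon
breakpoints are user-supplied BED input. mirSVR/miRanda scores are not
computed; a user-supplied score column can be joined and thresholded
downstream, but no such scoring ships here.

**Mutagenesis**: `mutate_site` complements the three span bases pairing
miRNA positions 3-5 — enough to destroy the seed match while leaving flanks
untouched, so non-overlapping sites of any miRNA are preserved. For
repetitive (AT-rich) seeds this exact substitution can recreate a shifted
copy of the seed core; the implementation then escalates deterministically,
complementing further core positions one at a time until no seed-core
occurrence overlaps the original span. The real constructs' mutated bases are
not published; this rule is a synthetic stand-in and is labelled as such.
Stale coordinates (region content no longer matching the recorded site
sequence, e.g. an already-mutated span) raise.

## Determinism and formats

All randomness flows from one integer seed through fixed-offset substreams
(`numpy` `default_rng([seed, stream, ...])`), so every table and the planted
truth are bit-reproducible; truth is emitted alongside every dataset. Tabular
outputs are TSV with `#`-prefixed `key=value` metadata headers (seed,
version, stage parameters) and floats at 6 significant digits; the pipeline
manifest records parameters and a sha256 per file with paths relative to the
output directory, so identical runs produce byte-identical manifests.
Sequences are FASTA; amplicons and sites are BED.

## Problem sizes used by the property studies

The benchmark/acceptance studies run at: 200 random scanner cases (regions
<= 2 kb); full 810-mimic noise-free inversion across all eight screens; 10
seeds of full four-assay panels for consensus recovery (at the boundary
condition `suppressor_effect = -1.5`, `global_shift = -0.2`, default noise);
20 seeds for null core calibration; 1000 zero-effect verification tests (50
plates of 20 candidates, 6 wells each); 500 cohort simulations for the
coupling study; 100 random p-vectors plus 200 seeds x 100 features for the
FDR filter; 100 random mutagenesis fixtures; and two full pipeline runs for
manifest determinism. The full suite completes in well under a minute of
simulation time on one core.

## Known limitations

* The simulator models no spatial slide artifacts, no plate-position
  effects, and no antibody cross-reactivity; its noise magnitudes are chosen
  for qualitative fidelity (broad mild suppression, a minority of strong
  coherent hits), not fitted to the unpublished raw data. Passing
  planted-recovery tests therefore demonstrates correctness of the analysis
  chain, not performance on real slides.
* Verification pools wells across biological replicates rather than
  modelling them hierarchically.
* Seed matching is exact Watson-Crick only: no wobble pairing, no
  3'-supplementary sites, no thermodynamic or conservation scoring, no
  isomiRs.
* ddPCR is simulated and analysed at the copy-estimate level; droplet-level
  Poisson concentration estimation is out of scope.
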