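# Methods

This note documents the models, estimators and numerical conventions
implemented in `asreg`, the assumptions behind the synthetic-data
generator, and the design choices made where the analysis design was
genuinely open.

## Synthetic screen model

The generator emulates a terminator-insertion antisense screen. Each gene
carries a latent expression level `E_g = 2^(μ + σ_expr·z_g)` (defaults
μ = 13 log₂ a.u., σ_expr = 1), modulated per growth condition by
`2^(σ_cond·z_gc)` (σ_cond = 0.2). A single-cell GFP intensity in a well is

```
gfp = w · (b + E · 2^(σ_cell·z))        sample cells
gfp = w · b                              reference cells
```

with cell-to-cell noise σ_cell = 0.35 log₂ units (≈ 25% CV, typical of
yeast protein reporters), autofluorescence background
`b ~ N(100, 10) a.u.`, and one multiplicative well factor
`w = 2^(σ_well·z)` (σ_well = 0.15) shared by sample and reference cells.
Because `w` multiplies every intensity in the well, the reference-median
normalization cancels it exactly — this is the property the co-culture
design exploits, and the generator encodes it deliberately rather than
approximately.

Antisense repression is planted by dividing `E` by `2^effect` in the two
antisense-carrying constructs (`PHO5_T_scr`, `WT`); the default effect is
1.0 log₂ units (2-fold), the screen's reported average. On/off genes set
the antisense-present expression to zero above background: the on/off
notion is defined relative to the detectability threshold, not a
biological zero. When regulated genes are chosen by fraction rather than
explicitly, sampling is weighted 3:1 toward TSS-overlapping antisense and
inversely to transcript length, planting the category enrichment and the
length contrast that the feature analyses test for. A per-(gene,
condition) effect override supports condition-specific scenarios; the
magnitude of condition-specific effects is not constrained by the
emulated study, so no distribution is imposed — the override is explicit.

Cell counts default to 300 sample + 300 reference cells per well, two
replicate wells per construct ("two biological replicates of each
strain"), four growth conditions (YPAD, YPGal, YPE, SC), a panel of
81/81/26 genes across the three annotation categories.

What the generator does *not* emulate: segmentation artifacts and
mis-assigned cells, plate/day batch effects beyond the per-well factor,
non-multiplicative (additive stray-light) backgrounds, PCR-error strains
(these appear in the analysis only through the replicate-discordance QC
rule), and any probe-level transcript quantification — sense/antisense
abundances are emitted directly at transcript level. Passing tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every real-data pathology.

## Normalization, threshold and QC

Per well: `sfgfp_norm = median(sample gfp) / median(reference gfp)`.
Medians, not means, on both sides — robust to segmentation outliers.
Ratio (not subtraction) normalization makes the summary dimensionless and
reproduces `sfgfp_norm ≈ 1` for unexpressed genes.

The expression threshold θ is the 99th percentile of null `sfgfp_norm`
values obtained by splitting each well's reference population in half and
normalizing one half against the other, pooled over 5 independent splits
(pooling reduces the quantile's Monte-Carlo error; the emulated study
does not describe how its threshold was determined). A construct is
"expressed" when its mean `sfgfp_norm` over passing wells strictly
exceeds θ; a gene × condition enters testing when the terminator and/or
scrambled-control construct is expressed.

QC fails a well with ≤ 100 sample or reference cells (strictly more than
100 required), with a missing population, or — jointly with its sibling
replicate — when expressed replicates of one construct differ more than
2-fold in `sfgfp_norm` (a guard against PCR-error strains; the 2× factor
echoes the 50%-range logic used for the scr/WT comparison and is a config
knob).

## Regulation calling

Observations are per-well summaries, not per-cell values: cells within a
well are pseudoreplicates, and wells are the unit of biological
replication. Per gene × condition, log₂ `sfgfp_norm` is regressed on a
construct indicator by OLS; with 2 + 2 wells this reduces to the pooled
two-sample t-test with 2 degrees of freedom. Non-positive summaries are
floored at θ/10 before the log (flagged). The call requires, jointly:

* p < 0.01 (strict; no multiple-testing correction in the call itself —
  BH q-values are attached for information only);
* scrambled control within a 50% expression range of `WT`
  (max/min ≤ 1.5, boundary inclusive; vacuously true, flagged, when `WT`
  is unmeasured);
* |mean(scr) − mean(T)| on the log₂ scale strictly greater than the
  larger within-construct replicate range (false if a replicate is
  missing);
* the gene expressed in at least one of the paired constructs.

On/off calls are regulated genes whose antisense-present construct is
below θ while the terminator construct is expressed; their fold change is
recomputed with the unexpressed construct floored at θ, making the
reported value a detectability-limited lower bound rather than an
estimate. Screen-level effect-size summaries consequently exclude on/off
calls.

Condition-specific regulation: for a gene regulated in c₁ but not in a
tested c₂, replicate-paired well differences (scr − T, log₂) are compared
between conditions by a two-sided Welch t-test at p < 0.05. The emulated
study names no procedure for this comparison; the Welch test on
well-level differences is this package's choice and is isolated behind
the module interface.

Under the null, the raw-p component of the call is exactly nominal
(fraction of false calls ≈ 1% at p < 0.01) and the auxiliary criteria are
essentially inactive at realistic well precision — once t exceeds the
2-df critical value the construct difference dwarfs replicate ranges. The
procedure's null call rate therefore sits at, not below, the significance
level; the auxiliary criteria exist to remove artifact classes
(inconsistent strains), not to tighten type-I control.

## Noise analysis

Gating: events are binned on a 64 × 64 (FSC, SSC) grid and the smallest
set of densest bins covering ≥ 10% of events is kept (mode-centred gate;
retention fraction and grid are config knobs — the gate geometry of the
emulated protocol is unpublished). The gate is deterministic and
invariant to event order. Note that the gate is not idempotent by
construction: re-gating a gated sample again keeps the densest ~10% of
the subset; re-gating does always return a subset of the original gate.

CV% = (SD/mean) × 100 with the n−1 SD, computed on gated, untransformed
GFP values. The abundance trend is fitted to (log₁₀ mean, log₁₀ CV%²)
points of all gene × construct samples by IRLS with Tukey bisquare
weights (tuning 4.685, coefficient-change convergence at 1e−8, ≤ 50
iterations); on non-convergence the fit falls back to least absolute
deviations and is flagged. `CV_res` is the vertical residual to that
line; because residualization orthogonalizes against abundance, `CV_res`
is uncorrelated with log₁₀ mean on the fitting set (checked as
|Spearman ρ| ≤ 0.05 at 300+ samples). The regulated vs non-regulated
comparison of gene-wise ΔCV_res uses the shared Wilcoxon rank-sum engine:
exact null for combined n ≤ 20 without ties, normal approximation with
continuity correction otherwise. The comparison's conclusion (sign and
significance) is invariant to replacing the robust fit by OLS or LAD on
default synthetic data.

The FACS generator draws GFP log-normally with mean set by the planted
expression and CV² = (a/mean + b) · 10^η, a = 400 a.u., b = 0.01
(CV ≈ 15–50% over the panel's expression range), with the gene-wise
excess η ≥ 0 drawn half-normal (scale 0.15 decades) and shared between a
gene's two constructs. Planted denoising multiplies the regulated scr
sample's CV² excess above the trend by `denoise_factor` on the linear
CV² scale. FSC/SSC form one log-normal cloud independent of GFP, so
gating is exercised without altering the planted GFP law.

## Metagene profiles

Coordinates are 0-based half-open throughout; GFF3 is converted at the
boundary (1-based closed → half-open), BED/bedGraph are half-open
already. Rows are extracted in transcription direction around the TSS or
stop-codon anchor (anchor at relative position 0; minus-strand genes are
coordinate-flipped), from strand-resolved antisense read-density tracks
or unstranded histone-mark tracks binned at 10 bp; the default window is
±500 bp. Positions outside the chromosome are absent-coded (NaN), never
zero-filled, and absent columns propagate through summaries.

Group summaries: column-wise median over present values followed by a
centred running mean of 5 bins (shrinking at edges and around absent
columns), or the bootstrap mean with percentile 95% CI from 1000
row-resamples (percentile, not BCa — nothing in the emulated analysis
requires more, and percentile intervals are transparent). Peak
localization takes the profile argmax with ties broken toward the anchor
(smallest |position|, then the smaller coordinate). Per-gene track
scaling before group summaries is available but off by default.

Known limitation: the percentile bootstrap undercovers for small groups
(measured ≈ 92% at 30 rows, ≈ 94.7% at 80 rows against a nominal 95%);
CI ribbons for groups of fewer than ~50 genes should be read as slightly
anti-conservative.

## Feature statistics

TSS-overlap classification: `NO_AS` without an antisense interval,
`TSS_OVERLAP` when the half-open antisense interval contains the sense
TSS, `NO_TSS_OVERLAP` otherwise; same-strand "antisense" is an annotation
error. Fisher's exact test uses the probability-based two-sided rule with
the conditional-MLE odds ratio. Spearman correlations use average-rank
ties, with an exact permutation p for n ≤ 9 and the t-approximation
above (the switch is recorded in the result). Site counting intersects
half-open intervals on the strand opposite the sense gene. Length and
noise comparisons share one rank-sum implementation.

## Orchestration and reproducibility

One YAML config (unknown keys rejected) drives a `screen`-style CLI with
per-stage subcommands; every stage accepts its input table directly, so
the imaging stage — a deliberately simple Otsu/connected-components
stand-in, thresholded in the log-intensity domain because cell brightness
spans decades — can be bypassed with externally quantified CellTables.
All randomness flows from `numpy` `SeedSequence`s spawned off one seed;
identical configs reproduce every output byte-identically, verified via
per-file SHA-256 checksums in the run manifest.

Default problem sizes (2000-gene null calibration screens, 160-gene
effect-recovery screens, 66 genes × 10⁵ events for noise, 90-gene track
panels) were chosen so each check completes in seconds to a couple of
minutes on a single core while keeping Monte-Carlo error well inside the
bands being tested.
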