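# Methods

This note records the models and procedures `gcexpose` implements, the
assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Data model

A feature table is an accurate-mass feature × sample intensity matrix.
Missing intensity is a first-class state (NaN), distinct from zero: a
peak not detected by the picker is *absent*, and blank filtering and
correlation exclude it from computation rather than imputing 0. Treating
absence as zero would bias the 10-fold blank ratio (a feature absent from
blanks would look identical to one measured at zero) and deflate
cross-sample correlations.

Retention time is stored in minutes everywhere; tolerance parameters that
are conventionally quoted in seconds (`rt_tol_s`, the 30 s match window)
accept seconds and convert at the boundary. m/z tolerances are expressed
in ppm of the *library* (theoretical) m/z, window closed at both ends, so
each chemical's acceptance window is fixed rather than drifting with the
observed mass.

Sample roles are `study`, `srm_1957`, `srm_1958`, `method_blank`,
`solvent_blank`, `isooctane_blank`. Only saline method blanks enter the
blank-filter denominator; solvent and isooctane blanks are baseline
references in the QC report. Whether SRM samples count as "nonblank" in
the filter numerator is not dictated by the batch design; the default
includes study + both SRM roles and is configurable
(`numerator_roles`).

## Blank prefilter

Retain a feature iff `mean(nonblank) > fold × mean(method blanks)` with
`fold = 10`. The inequality is **strict**: a feature exactly at the
boundary is removed. Ties at the boundary are vanishingly rare in real
intensities; the strict reading is the conservative one and is
configurable through `fold`. An all-missing blank mean is defined as 0,
so a feature absent from every blank passes whenever it carries any
signal. The filter is per-feature and idempotent.

## Targeted identification

Identification requires ≥ `min_fragments` (default 3) library fragments
each matched by a feature within ±5 ppm and ±30 s. Co-elution is enforced
against the library retention time (all matched fragments inside the rt
window); an optional stricter mode additionally bounds the matched
fragments' mutual rt spread (`coelution_window_s`, default 6 s when
enabled). Tie-breaks when several features fall in one fragment's window
are deterministic: smallest |ppm error|, then smallest |Δrt|, then
highest mean intensity. Within one chemical a feature can satisfy only
one fragment; across chemicals a feature may support at most one
chemical's quantifier, conflicts resolved by the same key and reported.

Identification does not require the quantifier fragment to be among the
matches, but quantification does: a result without a matched quantifier
is identified-but-unquantified. This separates the detection claim (any 3
co-eluting fragments) from the measurement (base-peak intensity).

The retention-index scale is piecewise-linear interpolation between
anchor chemicals (strictly increasing rt and index), with linear
extrapolation from the terminal segment outside the anchor range, flagged
as extrapolated.

Recovery is computed as 100 × mean(processed analyte/IS ratio) /
mean(unprocessed analyte/IS ratio), the IS being the volumetric internal
standard added to the final extract; the standard error propagates the
replicate SEMs of numerator and denominator in quadrature.

## Pseudo-spectrum clustering

Similarity between features i and j:

    s_ij = exp(−(rt_i − rt_j)² / 2σ_rt²) · exp(−(1 − r_ij)² / 2σ_corr²)

with defaults σ_rt = 0.05 min, σ_corr = 0.5, and r the Spearman
correlation over shared non-missing, nonblank samples (blanks carry no
biological covariation; rank correlation is robust to the positively
skewed concentration distributions typical of population exposure data).
Pairs sharing fewer than 3 samples get similarity 0. Pearson mode is
available. Average-linkage agglomerative clustering runs on dissimilarity
1 − s with the tree cut at 0.5; clusters with fewer than 3 members are
discarded and their features reported as unclustered, so clusters +
unclustered partition the input. The upstream tool this stage emulates
does not publish fixed parameter values, so all four knobs are
config-exposed and `sweep_cut_height` reports the ARI-vs-cut-height curve
against known labels.

Weighted spectra: each member's peak weight is its mean nonblank
intensity times its mean correlation to the other members; non-positive
weights (uncorrelated members) are excluded from the spectrum and listed
in the record. MSP export writes `Name:`, an RT comment, `Num Peaks:` and
m/z–intensity pairs at 5/4 decimals; read∘write is the identity within
that printed precision. Cosine matching pairs peaks greedily (most
intense query peak first, nearest unused reference peak within ppm
tolerance) and scores Σ√(I_q·I_r) / √(ΣI_q·ΣI_r).

For large tables the pipeline clusters in rt slabs (default 2 min); each
feature is assigned to exactly one slab (half-open intervals), keeping
the partition property.

## Quantification

Single-point reference standardization: `conc = conc_ref × I_sample /
I_ref`, with `I_ref` the mean over the batch's SRM-1958 injections.
Because each sample uses its own batch's reference intensity, a global
multiplicative batch effect cancels exactly.

Two-point variant: unweighted line through (certified concentration,
measured intensity) for SRM-1957 and SRM-1958, inverted as
`(I − intercept)/slope`. If the x intercept is positive the line would
report zero concentration at positive signal over part of its range, so
the method falls back to single-point standardization against SRM-1958
(flag `x_intercept_fallback`). Numerical guard: an x intercept within
`1e-9 × conc_1958` of zero is treated as zero, since an exactly
proportional response produces an x intercept of ±1 ulp. Equal reference
concentrations or non-positive slope likewise fall back, with their own
flags. With zero intercept the two-point estimator reduces algebraically
to the single-point one.

External calibration: OLS of response on concentration over the dilution
series 0, 0.05, 0.1, 0.25, 0.5, 1, 2 ng/mL (n = 3 per level by default).
Linearity is the absolute Spearman statistic on (level, mean response)
pairs — exactly 1 for any strictly monotone response — screened at
> 0.98. The instrument detection limit is 3 × SD(responses at the lowest
nonzero level) / slope; the multiplier is configurable since detection
limit conventions vary. Negative predicted concentrations are floored at
0 and flagged rather than reported negative. Recovery adjustment of
external-curve results (dividing by a per-chemical fractional recovery)
is available but **off by default**: unidentified chemicals have no
recovery data, and reporting identified and unidentified results on the
same convention is the more interoperable default; when enabled the
choice is visible in the result method/flags.

Response factors: RF = mean isotope intensity in SRM-1958 / certified
mass fraction; `conc = I / RF`. Under a proportional response this is
algebraically identical to single-point reference standardization.

Cascade in `quantify_study`, per chemical and batch: two-point RS when
certified and detected in both SRMs → single-point RS against SRM-1958 →
external curve → response factor → unquantified with reason. "Detected"
in an SRM means the targeted match passed and the quantifier intensity is
present and positive in that SRM sample. Units follow the certified
references; mixing units across references is rejected. SRM injections
failing sentinel QC can be excluded via `excluded_srm_samples`.

Rank-correlation comparison between methods (`compare_methods`) returns
exactly ±1 when the two rank vectors agree (or reverse) element-for-
element, bypassing the one-ulp rounding of Pearson-on-ranks; otherwise it
reports the Spearman statistic. Chemicals with fewer than 3 shared
quantified samples are skipped with a note.

## QC

Total ion intensity is the per-sample sum of detected peaks (missing
excluded); all-missing samples are flagged with sum 0. Sentinel
monitoring matches a configurable list of matrix-interference-sensitive
chemicals (DDE, DDT, HCB, three BHC isomers, PCB-138/153/180,
PBDE-47/85/153, PBB-153 by default) in every SRM-1958 injection and
flags intensities missing or outside 0.5–2.0× the running median across
batches; the band is a reporting convention, config-exposed, since
monitoring practice sets no universal numeric limit. Batch-layout
validation checks per-batch role counts against the expected design
(1 × each SRM, 2 × each blank type per batch).

## Synthetic-data generator

The generator is the test bed: it emulates the acquisition the workflow
consumes, with ground truth sufficient to score every stage.

* Chemicals get 3–6 fragments (configurable) with m/z uniform in 85–850
  Da at ≥ 0.5 Da pairwise spacing and retention times uniform in
  3–24.37 min at ≥ 0.05 min spacing (rejection sampling; infeasible
  packing is rejected). The library carries the true values — it stands
  for a library built from authentic standards, which is noiseless
  relative to the study run.
* Response is linear per fragment: `I = rel_abundance × slope × recovery
  × conc (+ rel × intercept)`, slope uniform in 5·10⁴–2·10⁵ counts per
  ng/mL. Recovery is a per-chemical constant in 0.65–1.10, identical
  across samples in a run — consistency, not completeness, of recovery is
  what single-point quantification requires.
* Study concentrations are log-normal (default median 0.2 ng/mL, log-SD
  1.0), giving the positively skewed distributions seen in population
  biomonitoring. SRM-1958 emulates fortified serum (0.5–2 ng/mL true
  values), SRM-1957 nonfortified (0.05–0.5 ng/mL); certified reference
  values equal the true SRM concentrations.
* Noise: Gaussian m/z jitter (default 1.5 ppm, ~3.3σ inside a ±5 ppm
  window), Gaussian rt jitter (default 1 s), and multiplicative
  per-injection intensity noise (`intensity_cv`, default 0.1 — an
  assumption recorded in the config snapshot, not a measured fact). The
  reported per-sample intensity is the mean over `injection_replicates`
  (default 3) injections, matching designs where each plasma sample is
  injected three times and the measurement is the replicate mean.
* Background: 60 contaminant features by default, uniform in m/z and rt,
  log-normal low intensity, present in *all* injections including blanks
  — true negatives for the blank filter. Method-blank carryover (a
  configurable fraction of the batch's mean study signal) is off by
  default.
* Batch layout: per batch, 20 study samples + 1 SRM-1957 + 1 SRM-1958 +
  2 method blanks + 2 solvent blanks + 2 isooctane blanks. A per-batch
  response scale emulates instrument drift between batches.
* Determinism: one integer seed drives a numpy PCG64 generator; the
  algorithm and all noise settings are written to the YAML config
  snapshot.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, saturation/nonlinearity at high concentration,
retention-time drift *within* a run, correlated (co-exposure) chemical
concentrations, or matrix-dependent ionization differences between
specimen types. Passing tests therefore demonstrate correctness of the
computations under the stated response model, not robustness to every
failure mode of real acquisitions.

## Problem sizes used in tests

The test suite and acceptance script run at desk scale by design:
studies of 10–50 chemicals × 6–20 samples (up to ~2,000 features for the
noise-containment check), 100-instance oracle-equivalence sweeps, and a
20-chemical 2-minute-window clustering problem. These sizes exercise
every code path while keeping the whole suite around a minute; the
windowed clustering path is the mechanism that scales the same code to
~25,000-feature tables.

## Known limitations

* Raw-spectrum peak picking/deconvolution is out of scope; the package
  consumes peak-picked feature tables.
* Formula prediction and commercial spectral-library search are out of
  scope; cosine matching targets user-supplied reference pseudo-spectra.
* The clustering similarity form and its defaults stand in for an
  external tool whose exact parameters are unpublished; published
  cluster counts from that tool are not reproduction targets.
* Replicate-injection averaging happens at read time (before blank
  filtering) when `combine_replicates="mean"` is requested; averaging
  after filtering is not implemented since the filter operates on means
  either way.
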