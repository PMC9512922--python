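# Methods

This note documents the models, defaults and numerical choices behind
`dormaflux`, what the synthetic generators do and do not emulate, and the
design decisions taken where the analysis was genuinely open.

## 1. Forward model of an imaging session

Each acquisition consists of five frames on a CCD, generated as

| frame      | expected counts            |
|------------|----------------------------|
| probe      | G·B·(S + A) + D            |
| background | G·B·A + D                  |
| dark       | D                          |
| phantom    | G·B·C_ph + D               |
| rhodamine  | G·B·C_rho + D              |

with day gain `G` (dimensionless, default 1), peak-normalized Gaussian beam
`B(x,y)` (FWHM equal to the field width), true signal field `S`,
autofluorescence `A` (120 counts), dark offset `D` (100 counts), phantom and
Rhodamine B brightnesses `C_ph` = 8000 and `C_rho` = 6000 counts. Noise is
zero-mean Gaussian with SD √(expected counts) — a Poisson–Gaussian CCD
approximation at unit gain, chosen because it is standard detector behavior
and cheap to generate. Absolute count levels are free choices (no absolute
intensity units are meaningful for these probes); they were set in the
few-thousand range typical of cooled-CCD fluorescence at multi-second
exposures, giving per-pixel shot-noise SNR of ~20–40. Exposure times (2 s
2-NBDG, 5 s TMRE) are carried as metadata only; no exposure normalization
is applied.

The signal field `S` mixes a dim diffuse floor (20% of the field mean —
tumor tissue fluoresces everywhere) with a heterogeneous log-normal
component placed on the fraction of the field given by `coverage_fraction`.
Both the amplitude field and the coverage mask are independent
Gaussian-smoothed white-noise fields (correlation length 8 px); the mask
threshold is an empirical quantile, so realized coverage is exact up to
pixel quantization, and the mixture keeps the whole-field mean exactly at
`mean_signal`. Per-phase profile defaults encode only ordinal relations
(2-NBDG falls after oncogene ablation and, in the slow line, rebounds at
recurrence; TMRE rises through regression → dormancy → recurrence with
growing coverage); the numeric values are generator choices, not measured
quantities. The generator makes no attempt to model optics (PSF, depth),
vasculature or cell-scale texture, so passing tests demonstrate correctness
of the *analysis*, not realism of tumor microanatomy.

## 2. Correction chain

Processing inverts the forward model stage by stage:

1. **Dark/background subtraction** — subtract the scalar dark-frame mean,
   then the scalar dark-corrected background mean. Scalar (not per-pixel)
   subtraction is robust to animal repositioning between frames; its cost
   is a small beam-shaped autofluorescence residual `G·A·(B − B̄)` that
   remains in the image (~5% of signal at the field edge with the default
   A/S ratio). Negative pixels are clipped to zero (downstream pixel
   distributions need nonnegative support) and the clipped fraction is
   reported in `qc_flags`; on default synthetic sessions it stays below 1%.
2. **Flat-field** — the phantom is dark-subtracted, Gaussian-smoothed
   (σ = 5 px, to avoid amplifying phantom shot noise into the image) and
   normalized to unit mean; pixels where the normalized phantom falls below
   ε = 0.05 are flagged invalid rather than divided.
3. **Rhodamine calibration** — division by the mean (configurable to
   median) of the dark-subtracted, flat-fielded Rhodamine frame over valid
   pixels. A scalar factor was chosen over any wavelength-wise mapping.

The composition is exactly invariant to rescaling all laser-on frames by a
common factor, and to the generator's day gain. On default synthetic
sessions the calibrated image recovers the latent field up to one global
scale with a median per-pixel relative error below 5% (measured on pixels
with signal above 10% of the field mean, after rescaling by the median
truth/estimate ratio).

## 3. Pixel statistics and the blocked permutation test

Pixels are pooled across mice within a probe/timepoint; each pixel carries
its mouse label. Distribution displays are density-normalized histograms
(default 100 bins over [0, max]; presentation only) with the pooled mean
superimposed. All testing happens on raw, unbinned values.

The two-sample KS statistic D is compared against a permutation null whose
exchangeable unit is the **mouse**: a permutation reallocates whole mice
between the two group labels, preserving group sizes, and recomputes D on
the re-pooled pixels. When the number of distinct reassignments C(m₁+m₂,m₁)
is within the permutation budget the null is enumerated exhaustively and
the exact fraction reported; otherwise 1000 random reassignments are drawn
(without uniqueness enforcement) and the add-one estimator
p = (1 + #{D⁰ ≥ D}) / (n+1) is used, which can never return zero. Pixels
within a mouse share illumination, probe dose and physiology; simulations
with a strong mouse-level random intercept (log-normal, SD 0.4 on the log
scale) show the blocked test holding its 5% level while a pixel-level
permutation rejects >95% of true nulls. Note the discreteness of small
designs: with m mice per group the attainable p floor is 2/C(2m,m) (each
reassignment and its mirror give the same D), so 2v2 designs cannot reach
p < 0.05 — matching the practice of pooling ≥7 mice per timepoint.

Group-mean statistics operate on per-mouse means: Log2(mean₁/mean₂) with a
Welch two-sided t-test (unequal variances assumed, since group sizes of
5–10 mice give no power to verify homoscedasticity), and one-way ANOVA with
Tukey HSD (studentized range) for multi-timepoint comparisons. The PDF
overlay uses the pixel-pooled mean; the tests use per-mouse means — the
former describes the pixel population, the latter respects the mouse as the
experimental unit.

## 4. Volume trajectories, recurrence, survival

Latent per-mouse model (day 0 = dox withdrawal at the 5×5 mm trigger,
V₀ = 62.5 mm³): exponential decay with half-life h to a plateau at
`residual_fraction`·V₀ (reached at the nadir day h·log₂(1/residual)), then
exponential regrowth at `regrowth_rate` from a mouse-specific recurrence
day drawn log-normally (median `median_recurrence_day`, log-SD
`recurrence_spread` = 0.10). Defaults: fast line h = 3 d (nadir ≈ day 7,
80% volume loss at the first week's measurement), median recurrence 55 d;
slow line h = 12 d (nadir ≈ day 28), median 100 d; Etomoxir arm = fast-line
parameters with the median scaled by 1.59. Calipers are read on a
Mon/Wed/Fri grid with multiplicative log-normal noise (CV 10%) applied to
the volume and back-computed into axes (V = L·W²/2, random aspect ratio
1.0–1.3); recurrence before the nadir is rejected as unidentifiable.

**Recurrence rule.** The post-regression window opens when volume first
falls below 50% of day 0. Scanning forward, the dormancy baseline is the
*median* of the post-regression measurements seen so far (≥3 of them), and
recurrence is called at the first strictly increasing pair of measurements
that (a) both exceed baseline·(1 + δ), δ = 0.10, and (b) initiate a
sustained escape — no later measurement falls back below that threshold.
The recurrence day is the first day of the pair (conservative for RFS).
Two design points deserve emphasis. A *minimum*-based baseline is
unusable at 10% caliper noise: the minimum of ~20 plateau readings sits
1.5–2 SD below the plateau, putting the δ-threshold underneath the plateau
mean, where chance ascending pairs call false recurrences in most mice.
And even with a median baseline, a long dormancy offers ~20–30 chances for
a noise pair to clear a 10% margin; the sustained-escape condition uses the
fact that calling is retrospective (the full trajectory is available) to
reject transients that relax back. With these two choices the rule recovers
configured medians within ~1 measurement interval (fast 56 d, slow 102 d at
n = 200) with no false-early calls, and is exactly invariant to rescaling a
trajectory by any constant.

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the median RFS is the first time S(t) ≤ 0.5 (undefined if the
curve never crosses it), and mice with no qualifying pair are censored at
their last measurement. With no censoring the KM curve equals 1 − ECDF
exactly. RFS extension is reported as 100·(median_alt − median_ref)/median_ref.

## 5. Metabolomics

The generator draws log-normal abundances (within-group CV 20%) for a
69-metabolite targeted panel (45 acylcarnitines, 15 amino acids, 9 organic
acids; n = 5 per group), injects missing cells completely at random (5%),
and plants treated-group decreases in 8 acylcarnitines (log₂ effects −1.5
to −2.8, concentrated in long-chain species, as expected under CPT1
blockade) and 2 amino acids (−1.8, −1.5). All planted magnitudes clear the
volcano gate with margin; whether the *pipeline* recovers exactly 8 + 2 is
the end-to-end test.

Processing: (1) KNN imputation in metabolite space — distance is the
Euclidean distance over mutually observed samples, a missing cell takes the
mean of the sample's values across the k = 10 nearest metabolites; observed
cells are preserved bit-exactly. (2) Log Pareto scaling: log₁₀, mean-center,
divide by √SD per metabolite (zero-variance metabolites, detected with a
1e−12 tolerance, scale to zero with a warning). (3) Outlier removal:
samples whose Hotelling T² on the first two PCA score dimensions exceeds
the 95% limit of the *internally studentized* null,
T²·n/(n−1)² ~ Beta(p/2, (n−p−1)/2). The more familiar F-form limit applies
to external observations and exceeds the largest attainable internal T²
(n−1 per component) at n = 10, which would mask every outlier; the beta
limit flags a 6-SD planted outlier >95% of the time at a ≤5% per-sample
null rate. (4) Volcano: log₂ fold-change of group means on imputed *raw*
abundances, two-sided Welch t-test on log values, significant iff
|log₂FC| > 1 **and** p < 0.05. No multiple-testing correction is applied in
the volcano — the filter is deliberately the conjunction of a raw p-value
and a fold-change gate, and should be read as descriptive, not
FWER-controlled.

## 6. Enrichment

Expression is normalized per gene by its maximum (all-zero genes dropped
with a warning), genes ranked by log₂(meanA/meanB) of normalized values
(pseudo-count 1e−6; exact ties broken lexicographically for determinism).
The enrichment score is the signed extremum of the classic one-sample KS
running sum — the member-rank ECDF against the uniform ECDF over all N
ranks (+1/|S| − 1/N at members, −1/N elsewhere; the walk ends at 0). A set
occupying the top k of N scores 1 − k/N. The score depends on the ranking
only through gene order, so it is invariant to monotone transforms of the
metric. Nominal p-values come from 1000 random same-size gene sets,
compared on |ES| (two-sided in enrichment direction), with the add-one
estimator; NES = ES / mean|ES⁰|. Gene-label permutation is a deliberate
divergence from phenotype-permuting GSEA: with 5 samples per group there
are only 126 distinct phenotype splits, too few for a stable null. The
weighted (|metric|-weighted increments) variant is available behind a flag
but is not the default.

## 7. Orchestration, seeding, determinism

Every generator and test takes an explicit seed; the pipeline fans one
global seed into per-stage children via
`numpy.random.SeedSequence((seed, stage_index))`, so stages are
independently reproducible and a rerun with the same configuration is
byte-identical in its CSV outputs. Each run writes a manifest carrying the
full configuration and its SHA-256 hash. Configuration files are YAML with
strict key validation (unknown keys are an error naming the key).

## 8. Problem sizes

Defaults used by the test suite and the endpoint-reproduction script:
256×256 px sessions; 200-mouse cohorts for recurrence/survival recovery
(11 for the regression-depth check, matching the imaging cohort size);
200 replicate metabolomics experiments for modal volcano counts; 500
simulations for permutation-test calibration, with 5 mice per group and
~120 pixels per mouse. These sizes give Monte-Carlo error comfortably
inside each check's tolerance while keeping the whole suite in the
low minutes on one CPU.

## 9. Known limitations

- The imaging generator is ordinal-faithful only; absolute intensities,
  dynamic range and noise couplings of a real instrument are not modeled.
- Scalar background subtraction leaves a beam-shaped autofluorescence
  residual (§2); with per-pixel background registration this would vanish,
  but repositioning between frames makes per-pixel subtraction fragile.
- No image registration across imaging days, no spectral unmixing, no
  probe crosstalk correction.
- The recurrence rule's sustained-escape condition is retrospective; an
  online (prospective) variant would trade specificity for latency.
- No mixed-effects modeling of pixel data; the blocked permutation test
  treats mice as exchangeable blocks and nothing finer.
- Differential-expression modeling and pathway over-representation are out
  of scope; the enrichment stage consumes expression matrices directly.
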