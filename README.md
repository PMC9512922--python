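# dormaflux

Quantitative analysis for longitudinal dual-probe metabolic imaging of
breast-tumor dormancy and recurrence.

In doxycycline-inducible Her2+/Neu mammary tumor models, withdrawing dox
ablates the oncogene: tumors regress to a small residual population, persist
dormant for weeks, and spontaneously recur. Intravital fluorescence
microscopy through a mammary window chamber tracks the two major axes of
tumor metabolism across this cycle — glucose uptake via the fluorescent
glucose analog 2-NBDG and mitochondrial membrane potential via TMRE, each
summarized by its signal 60 min post-injection (2-NBDG₆₀, TMRE₆₀).
`dormaflux` implements the full analysis chain for such a study, together
with a synthetic-data generator that emulates every input with known ground
truth, so the entire pipeline is testable without any animal data.

## What the package computes

**Image correction and calibration** (`dormaflux.correction`). Raw frames
are corrected as

    I_cal = [ I_probe − d̄ − b̄ ] / B̂ / r

where `d̄` is the mean of the laser-off dark frame, `b̄` the mean of the
dark-corrected pre-injection background frame, `B̂` the smoothed,
unit-mean uniform-phantom image (flat-field, removing the Gaussian beam
shape), and `r` the mean of the dark-subtracted, flat-fielded Rhodamine B
standard imaged in the same session (removing day-to-day system gain).

**Pixel-distribution statistics** (`dormaflux.stats`). Calibrated pixels
from all mice at a timepoint are pooled; two timepoints are compared by the
two-sample Kolmogorov–Smirnov statistic D = supₓ|F̂₁(x) − F̂₂(x)| with a
*mouse-blocked* permutation null: whole mice, with all their pixels, are
exchanged between group labels (n = 1000 permutations, or exhaustive
enumeration when the design admits fewer reassignments). Pixels within a
mouse are strongly correlated, so permuting pixels directly is
anticonservative by an order of magnitude — the package ships the naive
test only as an invalid comparator. Group means are compared by
Log2(mean₁/mean₂) with Welch t-tests, and one-way ANOVA + Tukey HSD.

**Tumor-volume and survival analysis** (`dormaflux.survival`). Caliper
volume V = L·W²/2 (W the smallest axis); recurrence is called after two
consecutive increasing measurements that climb clear of the dormancy
plateau and stay there; recurrence-free survival (RFS) is summarized by
Kaplan–Meier curves and compared by the log-rank test.

**Metabolomics** (`dormaflux.metabolomics`). K-nearest-neighbor imputation
in metabolite space, log Pareto scaling (log₁₀, mean-center, divide by
√SD), Hotelling-T² outlier removal on the first two principal components,
and volcano analysis where significance requires both |Log2FoldChange| > 1
and two-sided t-test p < 0.05.

**Gene-set enrichment** (`dormaflux.enrichment`). Expression is scaled per
gene by its maximum, genes are ranked by fold-change between groups, and a
set's enrichment score is the KS running-sum extremum over the ranked list,
with gene-permutation p-values (1000 permutations) and NES = ES / mean|ES⁰|.

## Worked example

Simulate a control and a fatty-acid-oxidation-inhibited (Etomoxir) arm,
call recurrences, and compare survival:

```python
from dataclasses import replace
from dormaflux import synthetic
from dormaflux.survival import call_cohort, km_estimate, logrank_test, percent_increase_rfs

control  = synthetic.generate_volume_cohort(replace(synthetic.FAST_LINE,    n_mice=200), seed=4)
etomoxir = synthetic.generate_volume_cohort(replace(synthetic.ETOMOXIR_ARM, n_mice=200), seed=5)

calls_c, calls_e = call_cohort(control), call_cohort(etomoxir)
km_c = km_estimate(calls_c["time"], calls_c["event"])
km_e = km_estimate(calls_e["time"], calls_e["event"])
chi2, p = logrank_test(calls_c["time"], calls_c["event"], calls_e["time"], calls_e["event"])

print(f"median RFS: control {km_c.median_rfs:.0f} d, etomoxir {km_e.median_rfs:.0f} d")
print(f"increase: {percent_increase_rfs(km_c.median_rfs, km_e.median_rfs):.0f}%  (log-rank p = {p:.2g})")
```

prints

```
median RFS: control 56 d, etomoxir 88 d
increase: 57%  (log-rank p = 6.3e-103)
```

i.e. the fast-recurrence line recurs around day 55–56, and the simulated
Etomoxir arm (median recurrence scaled by 1.59) extends median RFS by about
4.5 weeks (~57%), recovered end-to-end through caliper noise, the
recurrence-calling rule and the Kaplan–Meier estimator.

The same workflow is available from the shell:

```bash
dormaflux simulate cohort --arm control --seed 1 --out run/cohort
dormaflux survival --calipers run/cohort/calipers.csv --out run/surv
dormaflux run --config configs/demo.yaml --out run/demo   # full pipeline
```

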