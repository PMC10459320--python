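# Methods

## Dispersion model

The package models the area of a dried blood spot as linear in sample
hematocrit, `A(Ht) = intercept + slope·Ht`, with defaults
`slope = −0.0070 cm²/Ht%` and `intercept = 1.32 cm²` (fitted for 50 µL of
blood on Whatman 903 cards; both coefficients, the volume and the substrate
label are configurable for other card/volume combinations). The model is
applied over `ht_domain = [20, 70]` Ht%, the individual hematocrit range
established for newborns including anemic and polycythemic extremes; the
linear law extrapolates harmlessly outside it and only fails where the
predicted area reaches zero (Ht ≈ 188% with the defaults), which is treated
as an error.

Everything else is exact algebra on this law. The correction factor is the
area ratio of unknown to calibrator, `CF = A(Ht)/A(Ht_cal)`, and the
corrected ("theoretical") concentration is `C_theor = C_exp · CF`. The
percentage relative error attributable to hematocrit alone is

    RE(Ht) = 100 · (A(Ht_cal)/A(Ht) − 1) = 100 · (1/CF − 1),

the error committed by *not* correcting. This closed form is forced by the
correction-factor definition: the measured concentration of a sample is its
true concentration scaled by `A(Ht_cal)/A(Ht)` (the punch of a small spot
holds more blood), so RE is its fractional over-read. It is strictly
increasing in Ht, zero at `Ht = Ht_cal`, and reproduces the documented
extremes (−17.80% at Ht 20, +16.87% at Ht 70 for Ht_cal 50%).

Tolerance bands invert RE analytically: the Ht at which RE equals ±e% has
spot area `A(Ht_cal)/(1 ± e/100)`, hence
`Ht± = (intercept − A(Ht_cal)/(1 ± e/100)) / |slope|`. Band endpoints are
kept unrounded internally; display rounding is half-away-from-zero to
2 decimals (the convention that matches every checked cell of the published
safe-Ht table — half-even agrees on all checked cells, so the choice is not
observable there).

Hematocrit is accepted in percentage points only; values in (0, 1] raise
with a hint about fractions instead of being rescaled silently.

## Neonate subpopulations and Monte Carlo

The registry covers term (35–42 gestational weeks, including late preterm)
and preterm (29–34 weeks) neonates at post-natal days 0, 1, 2, 3, 7, 14
and 28, with mean reference hematocrits
(term: 53, 51, 50, 49, 45, 42, 38; preterm: 50, 49, 47, 45, 44, 38, 31)
and SD 6 at every timepoint. Below 29 gestational weeks no reference
ranges exist and no subpopulation is offered. Within each subpopulation Ht
is modelled as Normal(mean, SD): real Ht distributions may be skewed, but
normality is the modelling assumption throughout, and sex is not a
parameter (the reference data show no sex effect). Draws are *not*
truncated to [20, 70] by default — with SD 6 the out-of-range tail mass is
negligible and truncation would silently bias exceedance probabilities; a
`truncate_to` switch enables truncated sampling for sensitivity analysis.
`sd_ht = 0` is allowed as a degenerate cohort for analytic sanity checks.

Cohort summaries report mean, SD and the 5th/25th/50th/75th/95th
percentiles of the relative-error distribution. Calibration sweeps
re-evaluate one seeded cohort across the `ht_cal` grid by default (the grid
moves the calibrator, not the babies; per-point resampling is available and
equally seeded). The mean-RE-vs-Ht_cal curve is strictly decreasing and its
zero crossing — the ideal calibration hematocrit — lies slightly *above*
the subpopulation mean: `E[1/A(Ht)] > 1/A(E[Ht])` by Jensen's inequality
(1/A is convex), and with SD 6 the gap stays below one Ht point.

The probability of correction is the probability that a subject's Ht
leaves the tolerance band: analytically
`Φ((Ht_low−µ)/σ) + 1 − Φ((Ht_high−µ)/σ)`, or by Monte Carlo as the
fraction of simulated subjects outside the band. The production scenario
size is 1,000,000 subjects per scenario; most tests run at 1e5–2e5 with
3-standard-error tolerances to keep the suite fast. All randomness flows
through `numpy.random.Generator` from explicit seeds; there is no global
random state anywhere.

## Screening classification

A marker is raw-positive when its experimental concentration strictly
exceeds the cut-off in the marker's direction (above for "up" markers,
below for the "down" marker C0); a value exactly at the cut-off is *not*
positive and falls in the alert zone. The alert zone covers concentrations
within `alert_fraction` (default 10%) of the cut-off on the negative side,
boundary included. Both conventions are switches on
`ClassificationPolicy`: `cutoff_inclusive_positive` moves equality to the
positive side, and `correct_all` extends Ht correction from alert-zone
samples to every sample (enabling positive→negative re-evaluation of
marginal positives; by default only alert-zone — hence raw-negative —
samples are corrected, so only negative→positive flips can occur, the
rationale being that where concentrations largely exceed their cut-offs the
Ht effect cannot change the decision).

The flip threshold solves `C_exp·A(Ht)/A(Ht_cal) = cutoff` for Ht in
closed form; "up" markers flip below it, "down" markers above it, and a
crossing outside (0, 100) Ht means no flip is possible. Cohort screening
reports per-marker counts (definite positive, alert zone, flipped, plain
negative, missing) that always sum to the cohort size; samples missing a
marker are counted, never dropped.

Cut-offs are inputs, not estimates: the packaged 33-marker panel ships the
published MS/MS cut-offs, and custom panels load from CSV/TSV
(`marker,cutoff,direction[,alert_fraction]`, direction tokens `up`/`down`).
No clinical decision logic beyond the cut-off comparison is modelled.

## Synthetic cohorts

The generator emulates a screening cohort with known ground truth. True
concentrations per marker are: planted definite positives, uniform within
30% beyond the cut-off in the marker's direction; planted alert-zone cases,
uniform inside the zone (uniform planting is chosen for test transparency,
not realism); and a log-normal negative background (concentrations are
positive and right-skewed) with default median `0.5·cutoff` for "up"
markers, `2·cutoff` for "down", and geometric SD 1.3, resampled to stay
strictly clear of the alert zone. A recipe whose background law places more
than `zone_leak_tolerance` (default 5%) of its mass beyond the alert
boundary is rejected as infeasible, as are planted counts exceeding the
cohort size.

Hematocrit comes from a weighted mixture of subpopulation normals; optional
anemic/polycythemic quotas (defaults 2%/2%, within the up-to-5% prevalence
reported for neonatal polycythemia) reassign a random subset of samples to
uniform Ht in (20, 35) and (65, 70). Draws are clipped to [1.5, 99.5] —
mass there is ~1e-7 — so the sample objects stay in their legal Ht domain
without breaking the bias identity. Measured concentrations are
`C_true · A(ht_cal_true)/A(Ht)`, the exact inverse of the correction
factor, so correcting with the true calibration hematocrit recovers the
truth to machine precision (`recovery_check`, asserted at ≤ 1e-12). The
default CLI recipe plants, per marker, the definite-positive and alert-zone
counts observed in a 10,018-sample national screening round (shipped as a
template; those observed counts are *emulation targets*, not reproducible
results, since the underlying dataset is not public) over a 90% term / 10%
preterm day-3 mixture — day 3 being the usual screening day and ~10% an
approximate preterm birth prevalence.

What passing tests show — and what they do not: the pipeline is exact and
self-consistent under its own assumptions (linear area law, normal Ht,
multiplicative area-ratio bias). Real DBS data add analyte-specific
blood-to-plasma partitioning, recovery and matrix effects, spot
inhomogeneity, skewed Ht distributions and sampling-time dependence, none
of which are modelled; a clean recovery here does not certify correction
accuracy on real cards.

## Numerical and design notes

* Display formatting: 2 decimals for Ht bounds, 3 for concentrations, 4 for
  probabilities; rounding half away from zero (stdlib `decimal`).
* Analytic and Monte Carlo correction probabilities are both exposed and
  must agree within binomial error — the closed form is the oracle for the
  simulation, and the simulation guards the closed form against band
  mis-inversion.
* Zero crossings of sweep curves are linear interpolations between grid
  points; the curve is exactly monotone for a fixed cohort because only
  `A(ht_cal)` varies along the grid.
* CLI seeds: one root seed per invocation, split per subpopulation with
  `numpy.random.SeedSequence`; derived seeds are reported in the outputs.
* Config is TOML (`[model]`, `[simulation]`, `[screening]`, `[report]`);
  CLI flags override file values.

## Limitations

No analyte-specific Ht effects (blood-to-plasma partitioning), no skewed or
empirical Ht distributions, no neonates below 29 gestational weeks, no
re-estimation of cut-offs, no second-tier testing logic, no figures (the
CLI emits data tables; plotting is downstream).
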