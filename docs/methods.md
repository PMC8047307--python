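# Methods

## Cumulative DVHs and their reduction

A `DVHCurve` stores the absolute volume (cc) receiving at least each dose on
a uniform grid starting at 0 Gy (default bin 0.1 Gy, matching typical
planning-system exports).  Reduction is linear interpolation in both
directions:

* `V_D` — interpolate the cumulative volume at dose D; 0 above the grid,
  total volume at 0 Gy.
* `D_V` — invert the curve at volume v.  Flat (tied) segments are inverted
  at their **highest** dose, which is deterministic, monotone-consistent and
  physically correct (the minimum dose received by the hottest v cc).
* `D_max` — the largest grid dose with positive volume, i.e. `D_V` as
  v → 0⁺.  This guarantees `D_max ≥ D_0.03cc ≥ D_V` for all larger v.

EQD2 uses the linear-quadratic conversion `EQD2 = D·(d + α/β)/(2 + α/β)`
with the per-patient fraction count and α/β = 3 Gy (late brain effects);
2 Gy per fraction is a fixed point.  D-metrics are converted by treating
each covering dose as a total dose delivered in the patient's fraction
count.  How `V_D` should interact with EQD2 is not standardised; we adopt
the self-consistent extension of transforming the dose axis point-wise and
evaluating V at the requested EQD2 level.  Both physical-dose and EQD2 modes
are exposed (`--eqd2/--no-eqd2`); physical dose is the default and no claim
is made about which convention underlies any particular published table.

## Synthetic cohort generator

No public dataset accompanies the half-brain analysis, so the generator is a
first-class, calibrated component.  Each side's half-brain cumulative DVH is

    V(d) = V_tail · S((D_c − d)/σ_tail) + V_bulk · S((D_b − d)/σ_bulk)

with S the logistic sigmoid: a ~3 cc near-plateau hot tail (the temporal
pole dose) over a several-hundred-cc low-dose bulk.  Curves are truncated
below 0.01 cc (so `D_max` is finite) and forced non-increasing.

Parameters and rationale (all config, not code):

* The tail is **pivoted at 1.2 cc**: `D_c = D_peak + σ_tail·logit(1.2/V_tail)`,
  so the sampled per-side `D_peak` *is* the half-brain `D_1.2cc`.  `D_peak`
  means are T-stage dependent (60.47 / 65.47 / 72.67 Gy for T2/T3/T4,
  within-stage SD 2.73 Gy, side correlation 0.3 via a patient-level random
  effect), reflecting dose escalation with tumour extension.
* `σ_tail` is log-normal across sides (mean 1.869 Gy, log-SD 0.65).  Its
  mean is calibrated so the reference gaps `D_max − D_0.03cc = 2.07 Gy` and
  `D_0.03cc − D_0.5cc = 5.58 Gy` are reproduced in expectation; its spread
  decorrelates neighbouring `D_V` metrics the way real plan-shape
  variability does, which is what lets the AUC screen distinguish grid
  points near the generating metric.
* The bulk centre sits `38.38 Gy` below `D_peak` (floored at 25 Gy so
  low-dose patients keep their full structure volume), σ_bulk = 3 Gy,
  calibrated to the reference `D_20cc ≈ 40.9 Gy`.
* The temporal lobe shares the half-brain tail shifted down by a
  half-normal dose offset (scale 3.23 Gy, mean 2.58 Gy → a ~3.4% mean
  `D_0.03cc` reduction) over a much smaller bulk a further 11.12 Gy lower.
  Because tail and bulk are both dominated point-wise, temporal `D_V` never
  exceeds the half-brain value (the nesting invariant).
* Structure volumes are bivariate normal per pair with left–right
  correlation 0.95 for half-brains — required to reproduce the whole-brain
  volume SD of 126.78 cc from the per-half SDs — and 0.8 for temporal lobes
  (head-size covariation; no published value).  Temporal volumes are floored
  at 25 cc to stay above the 20 cc metric grid.  The whole-brain curve is
  the sum of the two half-brain curves, so volumes add exactly.
* Injury per side is Bernoulli with `P = 1/(1+exp(−b0 − b1·X))`,
  `(b0, b1) = (−11.045, 0.138)` on the side's half-brain `D_1.2cc` by
  default (V-metric-driven models are supported for screening experiments).
  Under the defaults this yields a ~19% per-side and ~33% per-patient injury
  rate, close to the reference cohort's 34.5% incidence.

All sampling comes from one seeded `numpy` generator in a fixed documented
order, so cohorts are bit-reproducible.

**What the generator does not emulate.**  Mid-volume behaviour (3–10 cc) of
the temporal lobe is colder than the reference table (the two-component
family has no mid-dose shoulder), so mid-range percent reductions are larger
than published, though the qualitative ordering — small covering volumes
reduced by a few percent, 20 cc by ~46% — is preserved.  Metric SDs at
sub-cc volumes are somewhat smaller than published, which lowers absolute
AUCs (~0.70 vs ~0.83).  Passing tests therefore demonstrate correct
*behaviour* (calibration of targeted moments, nesting, recovery of the
generating coefficients, peak location) — not that the generator matches the
clinical joint distribution in full.

## Statistics

* CV = 100·SD/mean with the n−1 SD.
* Paired *t*: `t = mean(d)/(sd(d)/√n)`, df = n−1; zero-variance differences
  return a flagged degenerate result.
* "Reduction (%)" is the mean of per-case percentages (the only reading
  consistent with a reduction column that carries an SD), with zero-reference
  cases excluded and counted.  Each patient contributes two paired
  observations (left and right) by default; per-patient averaging is a
  switch (`unit=patient`), since the published unit of analysis (220
  patients vs 440 sides) is not stated.
* Chi-square association is Pearson's without continuity correction.

## ROC screening

AUC uses the rank (Mann–Whitney) formula with midrank ties — identical to
exhaustive pair counting.  Confidence intervals use DeLong structural
components with a normal approximation truncated to [0, 1]; degenerate
variance (AUC ∈ {0, 1}) collapses the interval and is flagged.  Youden
cutoffs scan all midpoints between consecutive distinct scores with integer
(exact) tie handling; ties are broken toward higher sensitivity, then the
lower cutoff.  The default analysis unit is the side for lateral structures
and the patient (max of sides vs any-side injury) for the brain; all outputs
are stamped with the unit and CI method.

## NTCP model

`LogisticNTCP` maximises the Bernoulli likelihood by Newton scoring (IRLS),
convergence at max |Δb| < 1e-8 within 50 iterations; the covariance is the
inverse observed information at the optimum.  Quasi-complete separation is
flagged (`separation_`), never silently "fixed"; the Wald summary refuses
non-converged fits.  No penalisation is applied, matching standard clinical
practice.  Tolerance points invert the single-covariate model,
`X_p = (logit(p) − b0)/b1`, with delta-method CIs
(`∇X_p = [−1/b1, −X_p/b1]`); response-curve bands apply the delta method on
the linear predictor.  Note that inverting a fit at small p can yield values
outside the physical domain (e.g. a negative volume for the `V_72Gy` model's
5% point) — this is honest extrapolation of the logistic form, not an error.
Multivariate screening across dosimetric metrics is deliberately not offered
(they are strongly collinear); the only multi-covariate path is the T-stage
adjustment check, which refits with the metric plus ordinal T stage and
reports whether T stage would be removed at p > 0.05.

## Numerical choices and problem sizes

Grids default to 0.03–20 cc (with 0.1 cc steps through 0.5–1.5 cc) and
40–80 Gy in 1 Gy steps; the synthetic dose axis spans 0–120 Gy at 0.1 Gy.
Calibration and screening tests use 2000-patient cohorts (4000 sides);
coefficient-recovery experiments use 20 seeds at 5000 patients; DeLong
coverage uses 1000 binormal cohorts of 100 + 100.  These sizes give Monte
Carlo error comfortably below the asserted tolerances while keeping the
default test run to a couple of minutes on one CPU.
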