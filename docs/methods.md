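# Methods

## The measurement model

All quantities derive from ¹⁴C scintillation counts normalized per 10⁶
cells. Counts convert to carbon amounts through the tracer's specific
activity SA (dpm µmol⁻¹):

    carbon [nmol C / 10⁶ cells] = 1000 · dpm / SA

Counts are assumed background-subtracted upstream; counting efficiency and
quench correction are out of scope. Pool masses follow from fixed carbon
weight fractions — carbon is taken as 40% of starch weight and 80% of TAG
weight:

    mass [µg / 10⁶ cells] = carbon [nmol] · M_C · 10⁻³ / fraction

**Carbon atomic mass.** The default is M_C = 12.0 g/mol rather than the
IUPAC 12.011. With 12.0 the conversion reproduces the published starch
masses at their printed precision (765 nmol C → 23 µg; 1850 nmol C →
55.5 µg); with 12.011 the second value is 55.5509 µg and would print as
55.6. The constant is a parameter of `ConversionConstants`, so 12.011 can
be requested explicitly. Note that the published TAG masses are *not*
consistent with the stated 80% rule (346 nmol C gives 5.19 µg, not the
published 5.6; 4 nmol C gives 0.06 µg, not 0.08). The package implements
the stated rule and reports 5.19; the constants were not adjusted to
reproduce those two numbers.

**Rounding.** All arithmetic runs at full double precision. One-decimal
rounding, half away from zero, is applied only in the reporting layer
(`render_partition_report`, `round_half_away`).

## The pathway partition

Daily TAG synthesis over days 1–8 of N deprivation is attributed to three
routes; all series are aligned on integer day boundaries.

* **From starch.** In each daily 24-h bicarbonate pulse experiment, TAG
  label present at label end reflects same-day synthesis, while label
  appearing later must have transited a storage pool. The day-*d* starch
  contribution sums, over all pulses, the (clamped) TAG increments
  observed on day *d* after that pulse's label end. Day 1 is zero by
  construction: conversion of material made before the first label end is
  unobservable in this design.
* **De novo direct.** TAG label at each pulse's label end.
* **De novo via polar lipids.** Per-day transfer fractions f(lag) are
  estimated from a chase of polar lipids (PLs) labeled with
  ¹⁴C-palmitate during day 1: f(lag) = ΔTAG(lag) / PL(label end), clamped
  at zero and with the running sum capped at 1. The via-PL series is the
  convolution Σ_{s<d} PLsynth(s)·f(d−s), with PLsynth(s) the PL label at
  label end of bicarbonate pulse *s*. An alternative flat estimate
  (total PL synthesis × a single cumulative fraction) is *not* used: the
  two disagree in the source material itself (70% of the stated 135 nmol C
  of new PLs is 94.5, while the published via-PL column sums to 85.9
  against a printed total of 85.6). The per-day convolution is the
  better-specified rule and is the one implemented.

Row closure (calculated total = sum of the three pathway columns) holds
exactly at full precision and is enforced by the `PathwayPartition`
invariant. The published starch column is itself inconsistent at the
rounding level (printed entries sum to 234.5 against a printed total of
233.8, and the printed per-day calculated totals sum to 355.3 against a
printed 354.3); the package reports full-precision sums and treats those
differences as source-data rounding, not as targets.

**Replicates and clamping.** Replicates are averaged (mean) before
differencing. Negative first differences — possible under measurement
noise — are clamped to zero in transfer series; the raw differences are
retained in `diagnostics`. With noise-free input the clamping is a no-op.

**Transfer efficiency.** `conversion_efficiency` is Σ sink increase / Σ
source decrease over a chase. The starch estimator pools starch with the
water-soluble fraction because soluble label converts onward into starch
during the chase; values above 1 (possible when label reaches the sink
from outside the source set) trigger a warning rather than an error.

**Pre-formed polar lipids.** The pre-N acyl chase yields a conversion
fraction (default conditions: 0.75 of the labeled PL pool reaches TAG by
day 8). Extrapolating that fraction to the whole membrane pool
(169 nmol C) would imply ~127 nmol C of TAG from pre-formed PLs — more
than the entire observed PL decrease (55 nmol C) — so homogeneous labeling
is flagged inconsistent and the realistic reading is that only a small,
rapidly turning-over PL subpool is labeled. How the 1 µM internal free
palmitate concentration maps to that subpool's carbon content is not
derivable from the published material; the package exposes it as the
explicit parameter `labeled_pl_carbon_per_uM` (default 6 nmol C per 10⁶
cells per µM, a documented convention chosen so the default estimate,
0.75 × 6 = 4.5 nmol C, sits below the published 5 nmol C bound). Every
assumption of this estimate is an argument, none is buried in the code.

## The synthetic-data generator

Label flow is a linear compartmental system dx/dt = A(t)·x, piecewise
constant in time, with the external tracer pool clamped (held at a fixed
level while the label is on, zeroed instantaneously at washout — cells are
washed twice in practice and residual medium label is ignored). Time is in
days with t = 0 at N-deprivation onset. Three gates modulate rates:

* photosynthetic uptake activity a(t): 1.0 pre-N, 0.5 on day 1, 0.1 on
  day 2, 0.05 afterwards;
* per-edge switches: growth (soluble → biomass) runs only while nitrogen
  is present; stress-induced PL synthesis bursts during day 1 (relative
  activity 1.0) and idles at 0.4 afterwards; starch synthesis runs fully
  until day 2 and at 0.1 afterwards; direct TAG synthesis runs fully until
  day 2 and at 0.25 afterwards;
* a hard TAG-onset gate: edges into TAG carry zero rate for
  t < `tag_onset_lag` (default 0.75 d, splitting the reported 12–24 h
  delay; configurable).

Default rate constants (per day): uptake 1.7 (on an external level of
1000), soluble→biomass 6.5, soluble→starch 2.0, soluble→PL 0.42,
soluble→TAG 0.055, starch→TAG 0.016, PL→TAG 0.1912
(= −ln(0.25)/7.25, chosen so a PL pool labeled just before N onset hands
75% of its label to TAG by day 8). A starch→CO₂ respiration edge exists as
a sensitivity knob but defaults to rate 0, keeping the default model
closed (label-conserving) after washout. These defaults were calibrated by
forward simulation to the qualitative kinetics the designs were built
around — starch label 753 → 1720 nmol C with ≥80% of the rise complete by
day 2 and a near-steady level afterwards; TAG label reaching ~400 nmol C
with <10% of its day-8 value on day 1; day-1-dominant PL synthesis
totalling ~131 nmol C. **They are a synthetic parameterization, not
estimates of algal physiology.**

Replicate noise is multiplicative Gaussian with coefficient of variation
0.10 (the order of published replicate scatter), truncated at zero;
multiplicative noise is used because published uncertainties scale with
the means. Identical seeds give bit-identical output.

What the generator does **not** emulate: cell-division dilution of label
(values are per 10⁶ cells and cell counts are outside the model), isotope
fractionation, light/dark cycles, enzyme-level (saturable) kinetics,
heterogeneity among polar-lipid species, and respiration by default.
Passing tests therefore demonstrate the estimators' correctness and noise
robustness under first-order well-mixed kinetics, not their accuracy on
any real culture.

**Structural closure gap.** On the default parameterization the
partition's calculated 8-day total undershoots the measured total by
~11% (noise-free). The gap is structural, not numerical: the measured
series includes conversion of label fixed *before* N onset (pre-N starch
and soluble pools), which the daily-pulse designs cannot attribute, while
the via-PL column partly double-counts transfer that the starch estimator
also sees. The same signature — a large day-1 undercount with
approximately compensating later terms — is visible in the published
table (day-1 measured 38 vs calculated 8). The budget-closure tests
assert the gap stays within 15%.

## Numerical choices

* Trajectories integrate with `scipy.integrate.solve_ivp` (DOP853,
  rtol 1e-11, atol 1e-13); correctness is checked against a matrix
  exponential on each constant piece (agreement required to 1e-8
  relative). An exact `expm` propagation mode exists and is used inside
  fitting loops, where thousands of small solves dominate runtime.
* Fitting uses trust-region-reflective least squares with non-negative
  bounds; residuals are weighted by inverse replicate SD floored at 5% of
  each pool's maximum (with a global fallback when a pool is identically
  zero). Eight seeded multi-starts by default, log-uniform over the
  bounds; ties break toward the smaller parameter norm; refitting from a
  solution returns it. Non-convergence flags the result instead of
  raising. Bootstrap intervals (default 200 draws) resample replicates
  within (pool, day) cells and are widened, if necessary, to contain the
  point estimate.
* Degenerate inputs raise typed errors: zero source decrease or zero
  label at label end (`UndefinedEfficiencyError`), malformed files
  (`SchemaError`, naming row and column), malformed configs
  (`ConfigError`, unknown keys rejected).

## Problem sizes

The validation study uses 20 seeds at CV 0.10 with 3 replicates — the
published experiments report means ± SD of three independent cultures —
and eight-day designs on integer-day grids; the 14-day chase follows the
corresponding published design. These sizes are the package's study
conditions; recovery under them is a few percent median relative error,
comfortably inside the 15% acceptance band.

## Known limitations

* The first-order model cannot represent preferential turnover within a
  single pool; the pre-formed-PL analysis therefore needs the explicit
  labeled-subpool parameter described above.
* The starch estimator attributes *all* post-pulse TAG appearance to the
  storage route; soluble-pool residue and pulse-made PLs contribute to it
  as well. On the default generator this bias is part of the documented
  closure gap.
* Attribution across overlapping chases assumes pulse experiments are
  independent; no cross-experiment deconvolution is attempted.
* Sub-day sampling is not used by the partition (series align on integer
  days); interpolation would only serve diagnostics.
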