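# Methods

This note documents the models, statistics and numerical choices behind
plasmaquant, and what the synthetic-data generator does and does not
emulate.

## Synthetic data

**Pharmacokinetic profiles.** Subjects follow a one-compartment model with
first-order absorption and elimination and optional lag:

    C(t) = F·D·ka / (V/F · (ka − ke)) · (e^(−ke(t−tlag)) − e^(−ka(t−tlag))),  t > tlag

with dose D in ng and apparent volume V/F in mL, so C is in ng/mL. The
closed form is degenerate at ka = ke, which the constructor rejects. The
analytic maximum sits at tmax = tlag + ln(ka/ke)/(ka − ke) and the analytic
exposure is AUC0−∞ = F·D/(V/F·ke); both are exposed as properties and used
as oracles in tests. ka ≫ ke in both presets, so the terminal slope
reflects elimination rather than absorption (no flip-flop kinetics).

Presets (`MET_LIKE`, `CFZ_LIKE`) place the noise-free kinetics near a
published 850 mg metformin / 50 mg canagliflozin single-dose study:

| preset | dose | V/F | ka (1/h) | ke (1/h) | t½ (h) | tmax (h) | AUC0−∞ (ng·h/mL) |
| --- | --- | --- | --- | --- | --- | --- | --- |
| MET_LIKE | 850 mg | 588 L | 0.57 | ln2/6.03 ≈ 0.115 | 6.03 | 3.5 | ≈ 12 540 |
| CFZ_LIKE | 50 mg | 149 L | 0.55 | ln2/8.19 ≈ 0.085 | 8.19 | 4.0 | ≈ 3 963 |

A single-compartment model cannot match that study's CFZ Cmax and AUC0−∞
simultaneously (the reported pair implies multi-compartment disposition):
the CFZ preset prioritises t½, tmax and AUC, and its noise-free Cmax
(~239 ng/mL) is consequently below the reported mean (~383 ng/mL). These
are simulator presets, not claims about the original volunteers, whose raw
concentrations were never published.

**Assay error.** Measured concentration = c·(1 + N(0, cv)) + N(0, σ_add),
truncated at zero; the default proportional CV is 5% with no additive term,
a typical plateau RSD for a validated LC–MS/MS assay. Values below the
LLOQ (50 ng/mL MET, 10 ng/mL CFZ) are *flagged* BLQ but retained, so BLQ
policies stay testable downstream. All generators take a `numpy`
Generator (or seed) and are bit-reproducible.

**Run tables.** Response ratios sit on a configurable true line
(slope·X + intercept — defaults are the published regression lines
Y = 0.0016X − 0.0088 for MET and Y = 0.0056X − 0.0036 for CFZ), scaled by
per-plasma-lot factors and perturbed by the error model; the IS area is
held at its nominal value so the ratio carries the noise. Additive error is
mapped through the slope so its units stay on the concentration scale.

**Chromatograms.** Gaussian peaks (default σ = 0.05 min) centred at each
transition's retention time on a 0–5 min axis sampled every 0.6 s
(501 points), amplitude proportional to concentration, plus optional white
noise on a flat baseline. Real chromatograms have tailing, drift and
co-eluting interferences; none of that is emulated, so passing tests here
demonstrate correctness of the *computations*, not robustness to ugly
peak shapes.

## Chromatographic measurement

The apex is the maximum intensity inside a retention-time window (default
±0.2 min). Peak bounds walk outward to the nearest flanking local minima
below 5% of apex height (or the trace edge); integration is trapezoidal
after subtracting the straight baseline joining the bound endpoints, which
makes the area exactly invariant to constant offsets. Height is measured
above that local baseline. S/N = height / SD of a peak-free noise region
(default the first 0.4 min); a zero-variance region reports infinite S/N
with a warning flag rather than an error. S/N ≥ 10 sets the LLOQ-supported
flag. The integration rule is deliberately simple — no smoothing, no
deconvolution of co-eluting peaks — and is validated against the analytic
Gaussian area A·σ·√(2π).

## Calibration

Weighted least squares of ratio on nominal via statsmodels WLS; weighting
`none`, `1/x` or `1/x2`. The module default is unweighted, consistent with
plain "linear regression" calibration; the pipeline config defaults to
`1/x2` because the simulator's error is proportional, making 1/x² the
variance-matched estimator — with unweighted OLS over a 100-fold range,
the fitted intercept's noise routinely pushes the back-calculated LLOQ
outside its ±20% band. r is the weighted Pearson correlation. Blanks and
zero samples never enter the fit.

Acceptance: per-standard back-calculated accuracy within ±15% of nominal
(±20% at the lowest level), bounds inclusive; the curve passes when ≥ 75%
of standards pass including the LLOQ-level and highest-level standards.
The 75% curve rule follows standard regulatory guidance. Negative
back-calculated concentrations are reported with a BLQ flag, out-of-range
values with an in-range flag set false.

## Validation statistics

accuracy% = 100·(mean found)/nominal; RSD% = 100·SD(n−1)/mean. Reported
percentages are rounded half-away-from-zero to two decimals (the
convention of validation tables; `ndigits=None` gives full precision).
Intra-day statistics use a single day's replicates; inter-day pools every
replicate of every day (n = replicates × days) rather than averaging day
means. Recovery is the ratio of mean extracted to mean post-extraction
response per level, with an across-level mean; the matrix factor is the
unnormalized per-lot ratio to neat solution (IS-normalisation can be done
by dividing analyte and IS factors externally); dilution integrity
multiplies the measured concentration back by the dilution factor before
judging accuracy. Stability is judged primarily against nominal (matching
how stability tables are printed), with the stressed/fresh ratio reported
alongside when a fresh reference is supplied. Selectivity thresholds are
20% of the LLOQ response for analytes and 5% for internal standards, the
usual regulatory convention. A missing QC level is reported in the battery
notes, not fatal; an unknown stability condition is an error.

## Non-compartmental analysis

BLQ policy: leading BLQ observations count as zero, embedded and trailing
BLQ are excluded. Cmax/tmax are the observed maximum (ties to the earliest
time). AUC uses linear trapezoids, with the logarithmic rule
(C₁−C₂)·Δt/ln(C₁/C₂) on strictly decreasing positive segments under the
default `linear_up_log_down` method — exact on mono-exponential decay,
while the pure linear rule over-estimates convex decays. λz is fitted by
OLS of ln C on t over candidate terminal subsets (last 3, 4, …, all
points strictly after tmax); the subset with the highest adjusted R² wins
and exact ties go to the larger subset (tolerance 1e−12). Non-negative
slopes are rejected as "λz not estimable". AUC0−∞ = AUC0−t + Clast/λz with
a warning when more than 20% of AUC0−∞ is extrapolated. Cohort summaries
report mean ± sample SD (n−1); a single-subject cohort prints SD 0.0.

## Pipeline

One pydantic-validated config (YAML-loadable) drives all stages; the run
log records the seed and a SHA-256 config hash, and identical config+seed
reproduce byte-identical CSV outputs. A failed calibration halts that
analyte's dependent validation/NCA stages. The canonical validation-table
rendering uses the four columns `level,mean_found_ng_ml,accuracy_pct,
rsd_pct` at two decimals.

## Problem sizes and test design

The test-suite and acceptance computations use deliberately small designs
that still pin the statistics: 6 replicates × 3 days × 4 QC levels for
batteries (50 seeds when checking statistical calibration of the accuracy
estimator), 200 subjects for cohort parameter recovery, 12-subject cohorts
in the acceptance script, and 20-seed Monte-Carlo means for S/N (whose
per-trace estimate is stochastic; its expectation, not each draw, is the
claim). Oracles are independent of the code paths they check: dense grid
search for tmax, zooming grid search for WLS, analytic Gaussian areas and
exponential integrals, and an explicit brute-force subset loop for λz.

## Known limitations

* One-compartment kinetics only; no multi-compartment or food-effect
  simulation, so CFZ-like Cmax is biased low as noted above.
* Gaussian peaks without tailing or drift; no peak deconvolution.
* Vendor raw files and mzML are out of scope; chromatograms are CSV.
* The r printed by a real study reflects its particular noise; with
  synthetic noise-free standards r = 1 by construction, so published r
  values are not reproduction targets.
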