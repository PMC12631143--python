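# Methods

This note documents the models, the numerical choices, and the design
decisions behind `ldmtx`, in the order the pipeline runs them.

## 1. Spontaneous-report signal detection

### Data model and cleaning

Input is the four-table ASCII dialect of spontaneous-report extracts
(DEMO/DRUG/INDI/REAC, `$`-delimited, keyed by PRIMARY ID and CASE ID).
Cleaning follows the standard sequence:

1. **Merge** the four tables into one record per report version.
2. **Drug-name normalization** through a bundled synonym table
   (brand/abbreviation/misspelling → generic, case-insensitive,
   whitespace-trimmed). Unmatched names pass through unchanged and are
   counted. The bundled table is a small deterministic stand-in for a
   drug-name NLP system; it covers the variants the synthetic generator
   emits plus a handful of comparators.
3. **Renal cohort filter**: keep cases whose *indication* preferred terms
   (PTs) fall under the two renal-impairment high-level term groupings
   ("Renal failure and impairment", "Complications of renal failure"),
   from a bundled synthetic MedDRA-like lookup (the licensed dictionary is
   not shipped).
4. **Deduplication** on CASE ID, keeping the highest PRIMARY ID — the
   current version of a versioned report.
5. **PT exclusion**: reaction PTs from non-adverse-reaction classes
   (product issues, social environment, injuries, poisoning, surgical
   complications, medical procedures) are purged; cases left with no
   reaction PT are dropped and counted as missing adverse-event
   information.

Missing or unknown fields (sex, age, dose, country) are never imputed;
they are carried as explicit "unknown" values and counted.

### Disproportionality statistics

For a target drug and each reaction PT, a 2×2 table (a, b, c, d) is built.
The **counting unit defaults to the case–PT pair**: each deduplicated case
contributes each of its reaction PTs once, so N is the number of case–PT
pairs and `a` is the number of reports of the (drug, PT) pair — matching
the "n reports" framing of published signal listings. Case-level counting
is available (`unit="case"`). The comparator is all other drugs *within
the renal cohort* (configurable by running without the cohort filter);
with which comparator the published analysis was run is not stated.

Three statistics are computed, each with the classic signal criterion:

| statistic | definition | signal criterion |
|---|---|---|
| PRR | (a/(a+b)) / (c/(c+d)), Pearson χ² | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
| ROR | ad/bc, Wald 95% CI on the log scale | a ≥ 3, CI lower bound > 1 |
| IC  | log2((a+0.5)/(E+0.5)), E=(a+b)(a+c)/N | a ≥ 3, IC025 > 0 |

with IC025 = IC − 3.3 (a+0.5)^(−1/2) − 2.0 (a+0.5)^(−3/2), the closed-form
shrinkage approximation to the 2.5th percentile of the gamma posterior of
the observed-to-expected ratio (the tests verify it against the exact
`Gamma(a+0.5, rate E+0.5)` quantile to within 0.15 bits for a ≥ 5).
A PT is a **signal** only when all three criteria hold. χ² is uncorrected
by default (the classic rule predates continuity-correction conventions);
a Yates-corrected variant is behind a flag. No multiplicity adjustment is
applied across PTs: the three-way rule is the operating control.

Degenerate tables: a zero margin makes the PRR undefined (flagged
invalid); `c = 0` with `a > 0` yields PRR = ∞; any zero cell triggers the
Haldane–Anscombe +0.5 correction for the ROR (marked `corrected`); the IC
shrinkage handles zeros natively.

## 2. Dose–Cmax restricted cubic spline

A 4-knot restricted cubic spline links weekly oral dose M (mg) to the
first-dose Cmax (µmol/L): `Cmax = β0 + β1·M + β2·f1(M) + β3·f2(M)`.
The basis uses truncated powers `(M−k)₊³` with boundary-knot weights that
make the curve exactly linear below k1 and above k4. Two conventions
matter:

* **Truncation.** Written without the `(·)₊` truncation the cubic terms
  cancel identically and the basis degenerates to a quadratic; the
  truncated form is therefore the only meaningful reading and is what is
  implemented.
* **Scaling.** Under the conventional scaling the basis is divided by
  (k4−k1)². With the reference coefficients (β0=0.0636, β1=0.0139,
  β2=0.0542, β3=−0.0912; knots 5/7.5/15/22.5 mg) the *unscaled* basis
  yields physiologically absurd predictions (>5 µmol/L at 10 mg), while
  the scaled basis yields plausible values (0.17 µmol/L at 7.5 mg), so
  `harrell_scaled` is the default and `unscaled` is kept for sensitivity.

Fitting is ordinary least squares on the 4-column design (1, M, f1, f2)
with knots at the 0.05/0.275/0.725/0.95 empirical dose quantiles
(overridable), scored by AIC = n·ln(RSS/n) + 2·4. Inversion
(dose attaining a target Cmax) is bracketed bisection to |f−target| <
1e−9 after a monotonicity check on a fine grid.

**Documented discrepancy (baseline dose).** Inverting the reference
spline at the 0.16 µmol/L cutoff gives ≈ 6.85 mg (the linear segment alone
gives (0.16−0.0636)/0.0139 ≈ 6.94), *not* the published baseline dose
m0 = 2.3 mg. The published derivation passes through an unspecified PBPK
verification step that is not reproducible from the printed constants.
The package therefore carries m0 = 2.3 mg as a configuration constant used
exactly where the published calculus uses it (the threshold scaling), and
asserts the inversion result as a recorded finding rather than forcing
agreement.

## 3. Minimal PBPK model of oral methotrexate

### Structure

Three mass states (gut depot, central, peripheral; amounts in µmol) plus
two bookkeeping states (cumulative eliminated, unabsorbed loss).
First-order absorption `ka` with bioavailability F; two-compartment
distribution (Vc, Vp, inter-compartment clearance Q); elimination from the
central compartment through four explicit linear routes:

* renal filtration `fu × GFR_abs` — absolute GFR from the BSA-normalized
  eGFR via the DuBois surface area of the individual;
* renal tubular secretion `CL_sec` — one lumped linear clearance for the
  basolateral-uptake (OAT3, RFC1) → apical-efflux (MRP4, BCRP) chain.
  Secretion is linear because low-dose exposures (≤ ~1.4 µmol/L) sit two
  orders of magnitude below the reported transporter IC50s (OAT3
  61.5 µM); no intracellular kidney compartment is modelled;
* hepatic metabolic clearance `CL_hep` and biliary clearance `CL_bile`.

This is a deliberately minimal lumped model: the mechanistic content is
the route decomposition and its renal-function scaling, not whole-body
anatomical physiology.

### CKD scaling (intact nephron hypothesis)

The transporter concentration ratio equals `eGFR_CKD / eGFR_ref` with
eGFR_ref = 106.78 mL/min/1.73 m² (healthy reference adult: 30 y, 176 cm,
73 kg). Filtration scales directly through the individual's absolute GFR,
secretion through the transporter ratio (and body surface area), and the
hepatic/biliary routes are left unscaled by renal function — metabolic
compensation retained — with a configurable multiplier for sensitivity.
Volumes scale with body weight; Q and the non-renal clearances with BSA.
CKD stage bounds (mL/min/1.73 m²): stage 1 simulated on [90, 106.78],
stage 2 [60, 89], 3a [45, 59], 3b [30, 44]. Virtual populations draw eGFR
uniformly within stage bounds and weight/height lognormally around the
reference adult (CV 15% / 5%).

### Parameter values

Defaults for the healthy reference adult: fu 0.54, ka 1.5 h⁻¹, F 0.85,
Vc 9.9 L, Vp 20 L, Q 4 L/h, CL_sec 5.8 L/h, CL_hep 1.0 L/h, CL_bile
0.4 L/h. Two published physiological constraints are enforced as hard
invariants at validation: the renal share of total clearance exceeds 0.8
(>80% of methotrexate is excreted unchanged in urine; here 0.87) and the
secretion share of renal clearance lies in [0.6, 0.8] (here 0.61).
Within those constraints the central volume was calibrated so that a
single 2.3 mg oral dose peaks at the 0.16 µmol/L exposure anchor
(simulated Cmax 0.160 µmol/L, tmax 0.7 h, terminal half-life ≈ 4.9 h —
consistent with reported low-dose oral methotrexate kinetics).

### Numerics

The system is linear, so propagation uses the matrix exponential of the
rate matrix over each grid step — exact for the stated model and
unconditionally stable; the default grid is 0.05 h over the dosing
horizon. The test suite checks the implementation against an independent
closed-form eigendecomposition solution (rtol 1e−8), mass balance at
machine precision (acceptance bound 0.1%), dose linearity to 1e−6,
superposition of repeated doses, and the filtration-only terminal slope
against the analytic two-compartment eigenvalue within 1%.

### Calibration and evaluation

`calibrate_healthy` minimizes the sum of squared log10 concentration
residuals (pooled over ≥ 2 doses) over a free-parameter subset (default
ka, Vc, Vp, Q, CL_sec) in log space under box bounds that keep the
physiological invariants satisfiable, with multi-start L-BFGS-B (first
start = supplied parameters, remaining starts seeded uniform in the log
box). Zero-noise synthetic observations are recovered within 5%
(clearances and Vc); at 20% multiplicative noise, within 15% across
seeds.

Model evaluation reports:

* **MRD** = 10^√(Σ(log10 Cpred − log10 Cobs)²/m) over matched
  concentrations. The square root is part of the established definition
  (without it the quantity is not a fold error); the printed-literal
  no-root variant is computable via `mrd_sqrt=False`.
* **GMFE** = 10^(Σ|log10(pred/obs)|/n) over per-study PK parameters
  (Cmax, AUC_last by linear trapezoid to the last observation). The
  absolute-value form is ≥ 1 by construction; because published values
  below 1 (e.g. 0.99) are only possible for the *signed* variant, the
  signed geometric mean fold ratio is reported alongside.
* goodness-of-fit fractions of concentration pairs within 2-fold and
  1.25-fold.

Sensitivity analysis reports central-difference log-log elasticities of
Cmax and AUC_last; analytic identities (F elasticity of AUC = +1,
clearance-route elasticities of AUC summing to −1, Vc elasticity of AUC
≈ 0) are verified in tests.

## 4. Risk thresholds and dose optimization

### Threshold scaling

`threshold(M, eGFR) = 0.16 × (M / 2.3) × (eGFR / egfr_norm)` µmol/L.

**Documented discrepancy (normalization).** The scaling equation is
published with eGFR_ref = 106.78, but only `egfr_norm = 90` reproduces the
published 7×4 threshold grid (e.g. 0.16 × 7.5/2.3 = 0.522 at eGFR 90
requires a unit ratio there). The default is therefore 90; 106.78 is kept
as an option, and a test asserts that the 106.78 variant reproduces *zero*
of the printed cells. Separately, two printed cells in the 20 mg column
(eGFR 89 → 1.377; eGFR 44 → 0.681) sit exactly 0.001 above the value the
formula produces (1.376, 0.680) while every neighbouring cell matches —
treated as print-rounding slips and asserted as such, not patched.

### Population assessment

For a (stage, dose) regimen, n virtual individuals are simulated for one
weekly dose; each individual's Cmax is compared with the threshold at
*that individual's own* eGFR. The exceedance fraction is reported and the
verdict follows the median individual (`exceeds` when more than half
exceed). Under the default calibration, stage 1 stays below the threshold
for all four label regimens while stages 2–3b exceed it, with the margin
widening as eGFR falls.

### Dose optimization

The PBPK model is dose-linear and the threshold is linear in dose, so
comparing a candidate dose's Cmax against a threshold re-derived from that
same candidate dose is dose-free — no reduction could ever change the
verdict. The implemented rule therefore anchors the risk bound to the
**prescribed regimen**: the bound is fixed at `threshold(initial dose,
anchor eGFR)` and the dose is stepped down in 2.5 mg tablets until the
simulated Cmax of the reduced dose falls below it. The anchor individual
is the reference adult at the stage's **midpoint eGFR** (the stage-typical
patient): anchoring at the stage's lower bound is arithmetically
incompatible with a one-tablet stage-2 reduction for the 7.5 mg regimen
(5/7.5 equals the 60/90 eGFR ratio exactly, so any Cmax inflation at all
overshoots one tablet), while the midpoint reproduces it robustly.
When even a single tablet exceeds the bound the optimizer reports a
minimum-dose failure rather than a dose; under the default calibration
this occurs for the 7.5 mg regimen at stage 3b, where the package's
optimization is more conservative than the published table (exact
regimen-by-regimen agreement depends on the unpublished calibration of
the source model and is not asserted; the ≤-initial, cross-stage
monotonicity and stage-2 one-tablet contracts are).

## 5. Synthetic data: what it does and does not emulate

The corpus generator emulates: versioned duplicate reports (same CASE ID,
increasing PRIMARY ID), drug-name variants needing normalization, a renal
indication subcohort (default 30% of cases), background reaction-PT
reporting rates with planted rate-ratio effects for chosen (drug, PT)
pairs, missing demographics, and the FAERS ASCII dialect. It does **not**
emulate: correlated PT co-reporting beyond what shared case margins
induce, reporting-rate secular trends, free-text drug strings beyond the
synonym table, probabilistic (non-key) duplicates, or the ~1.5M-case scale
of a real extract. Passing the planted-recovery and null-calibration
tests therefore demonstrates that the statistics and the three-way rule
behave correctly on well-specified corpora, not that real-extract signal
lists would be reproduced.

The PK observation generator simulates the reference adult and applies
unit-mean multiplicative lognormal noise (CV default 15%) — a stand-in
for digitized mean curves from published healthy-volunteer studies; it
carries no between-subject kinetic variability beyond the noise, so
calibration recovery quantifies estimator behaviour, not population
variability. The demographic fixture reproduces published column margins
exactly but draws the joint distribution independently per column (only
margins were published); the overlapping printed age-bin edges resolve to
the upper bin (65 counts as 65–100).

## 6. Problem sizes used

Default study sizes: 8,000-case corpora for pipeline runs (20 × 4,000 and
20 × 8,000 for the Monte-Carlo recovery and null-calibration checks);
1,000 virtual individuals per stage for population summaries (smaller
seeded samples in per-regimen assessments); 17 doses × 50 replicates for
spline recovery; two-dose, six-subject observation sets for calibration.
These sizes put every Monte-Carlo check comfortably in its asymptotic
regime while keeping a full run in seconds on one CPU.

## Known limitations

* The minimal PBPK model has no organ-level physiology, no metabolite
  kinetics, no saturable transport, and no drug–drug interactions; it is
  a route-decomposition model for exposure scaling across renal function.
* Transporter decline is assumed proportional to eGFR (intact nephron
  hypothesis); transporter-specific non-linear declines in CKD are not
  modelled.
* The risk calculus inherits the published constants' internal tensions
  (baseline dose vs spline inversion; normalization 90 vs 106.78); both
  are surfaced as tested findings rather than resolved.
* Dose-optimization outputs are anchored to a stage-typical individual;
  individual dosing decisions would require patient-specific eGFR.
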