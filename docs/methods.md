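# Methods

## Scope and data model

The package reduces doubly-labeled-water (DLW) raw inputs to total daily
energy expenditure (TDEE), derives the standard field-study energy budget,
classifies training courses into physical activity factors (PAF), and
evaluates/refits two linear prediction equations for daily energy
requirements. No individual-level data from the original pooled analysis of
133 special-operations trainees were ever deposited, so the published
course-level summary tables (`opsfuel.reference`) act both as fixtures and
as the parameterization of the synthetic-cohort generator.

## DLW kinetics

**Dilution.** Total body water in moles is computed from the printed
dilution form TBW = (A/MW_d)(APE_d/100)·18.02·[1/(R_std(E_s−E_p))]·(1/1.01),
with kg = mol·18.02/1000. Two deliberate contract choices:

* The formula is *unit-agnostic* in the enrichments: E_s, E_p and R_std must
  be supplied in mutually consistent units (the source text's enrichment
  unit is ambiguous), and only the sign of the gradient is validated.
* The 1/1.01 factor is the ¹⁸O dilution-space correction and is applied by
  default for either tracer, following the printed form; a 1/1.04 ²H
  dilution-space option exists (`use_h2_dilution_space`) but is off by
  default. TBW is taken from the ¹⁸O dilution unless requested otherwise.

In the composed pipeline the post-dose enrichment E_s is the zero-time
intercept of the elimination fit rather than the first raw sample: identical
for noiseless mono-exponential decay, and an averaging estimator under
assay noise.

**Elimination rates.** k is minus the OLS slope of ln(enrichment − baseline)
against time over all usable post-dose samples. Samples at or below baseline
carry no tracer signal; they are dropped with a warning, and fewer than two
usable samples is an error rather than a silent two-point fallback.

**CO₂ production and energy.** rCO₂ = (N/2.078)(1.01 k_O − 1.04 k_H) −
0.0246·rH₂O_f with rH₂O_f = 1.05·N·(1.01 k_O − 1.04 k_H). Negative
production (1.01 k_O < 1.04 k_H) is reported as-is with a warning, never
clipped, because it signals inconsistent enrichments the analyst must see.
The kcal-per-mole constant is not printed in the source; it is derived from
the cited Weir relation — energy per liter CO₂ = 1.106 + 3.941/RQ — times
the 22.414 L/mol molar volume, giving 127.50 kcal/mol at the default RQ of
0.86 (the food quotient of mixed field rations). RQ is validated to the
physiologic range [0.7, 1.0].

## Energy budget

FFM = TBW/0.73 (73% hydration of lean tissue); FM = BM − FFM;
RMR = 370 + 21.6·FFM (a lean-mass regression appropriate to fit, active
adults); DIT = 0.10·TDEE; AIEE = TDEE − RMR − DIT (so the decomposition is
exact by construction); PAL = TDEE/RMR.

Energy balance is **intake − expenditure** (deficit negative). The source
table's footnote states the opposite order, but every printed value follows
intake − expenditure, and the printed values are the ground truth the
package matches.

Course summaries report mean and Student-t 95% CIs per quantity; n = 1
courses get a mean with CI set to NaN. Course-level PAL is the mean of
individual ratios (the natural per-participant aggregation), not the ratio
of course means; both are recoverable from the summary table.

## Activity factors and prediction models

`derive_paf_scheme` computes 25th/50th/75th percentiles of PAL with the
linear-interpolation quantile estimator (the most common default; the
estimator choice is untied from results because the published cutpoints
2.10/2.40/2.75 are frozen as `DEFAULT_SCHEME`). The printed category bands
leave gaps (e.g. 2.10–2.11); assignment uses half-open intervals with
inclusive upper bounds, which reproduces all 12 published course
assignments.

The published models (A: body mass + PAF; B: fat-free mass + PAF) are kept
at full printed precision and only rounded for report output (kcal to
integers, PAL to 2 decimals, masses to 1 decimal). PAF enters refits as a
numeric 0–3 covariate — a single slope, matching the published form — via
OLS; SEE = √(RSS/(n−3)). The measured-vs-predicted evaluation runs a
two-sided one-sample t-test of the per-course prediction errors with
Bonferroni correction (m = number of courses with n ≥ 2) plus a one-way
omnibus F across courses; the original analysis names a univariate ANOVA
without specifying its construction, so this is flagged as the closest
defensible reading, not a replication of unpublished software settings.

## Synthetic-data generator

* **Anthropometry/expenditure.** Per course, BM and FFM are drawn from
  independent normals at the published means, jointly redrawn until
  0 < FFM ≤ BM; SDs are reconstructed from the printed 95% CIs as
  half-width·√n/1.96 (normal-theory inversion, kept even at small n so the
  fixtures are exactly reproducible from the printed tables). TDEE is either
  normal at the published course mean or, for recovery experiments, a
  ground-truth prediction model applied to the participant plus
  N(0, residual_sd) noise. Intake, where the course collected it, uses the
  printed intake CIs the same way.
* **Course structure.** The energy tables split Small Unit Ranger Training
  into classroom and field phases sharing one anthropometry row (n = 13);
  the per-phase split is not reported, so the generator fixes 7/6, making
  the 12-course cohort total 133.
* **Isotope series.** The CO₂ equation constrains only
  1.01 k_O − 1.04 k_H, so the generator pins the remaining degree of freedom
  at k_O/k_H = 1.25 (a typical field ratio, configurable); zero-time excess
  enrichment is set by inverting the dilution equation at the configured
  body-water pool, keeping the forward model the exact inverse of the
  analysis. Noise is multiplicative on the excess enrichment (assay errors
  scale with signal), with an additive option; at zero noise the full
  pipeline returns the configured rCO₂ and TBW to machine precision.
* **Determinism.** All randomness flows from one `numpy` Generator seeded by
  the config; identical config ⇒ byte-identical output tables.

What the generator does **not** emulate: BM–FFM correlation within a course
(draws are independent normals), within-participant correlation between
expenditure and body size beyond the model-truth mode, day-to-day activity
structure (the PAF has no time domain), multi-compartment water turnover,
or intake reporting error. Passing tests therefore demonstrate correctness
of the arithmetic and estimators under the stated statistical structure, not
robustness to every feature of real field data.

## Numerical choices and degenerate inputs

* Elimination fits use `numpy.polyfit` on log-excess; tests cross-check
  against a closed-form simple-regression oracle at 1e-10.
* Zero enrichment gradient, non-positive body water, unphysiologic RQ,
  singular regression designs, all-equal PAL samples, and negative SDs are
  hard errors naming the offending quantity; sub-baseline samples and n = 1
  courses degrade gracefully with warnings.
* Rejection sampling for 0 < FFM ≤ BM caps at 1000 draws per participant;
  with realistic specs the constraint rarely binds.
* Generated TDEE is floored at 1 kcal/d and intake at 0 (guards against
  pathological configs; untriggered at the published parameter values).

## Known limitations

* The published per-course prediction table contains two internally
  inconsistent entries that no arithmetic on the printed inputs reproduces:
  the Platoon Raids row (printed activity expenditure and PAL contradict its
  own printed TDEE/RMR/DIT) and the Combat Dive Model B mean (the FFM
  implied by the printed prediction rounds to 63.7 kg, while the table
  prints 63.8). Both are excluded from reproduction checks and covered by
  dedicated tests demonstrating the inconsistency.
* Published overall-row AIEE and balance are means over differing
  participant subsets and cannot be recomputed from the printed overall
  means; they are not used as fixtures.
* Refitting the prediction models on synthetic cohorts recovers the slopes
  tightly, but the intercept of a model whose covariate centroid sits ~82 kg
  away from zero has a per-fit sampling SD of roughly 556 kcal/d at n = 133
  and residual SD 640 — intercept comparisons should always be read
  alongside that sampling error.
* The RMR used in PAL is estimated from FFM, not measured by calorimetry;
  the prediction equations inherit that approximation and are calibrated to
  male Army/Marine trainees of similar body composition.
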