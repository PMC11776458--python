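# Methods

## Estimand and estimator

The package estimates the effect of a one-unit increase in the log
Prevotella/Bacteroides ratio (MB) on the log-odds of an incident disease
(D), using the 10-year antibiotic prescription count (hAB) as an
instrument in a two-sample design. Stage 1 is ordinary least squares of MB
on hAB in the microbiome cohort; stage 2 is maximum-likelihood logistic
regression of D on hAB in the outcome cohort (Newton iterations,
convergence tolerance 1e-8, at most 100 iterations). The causal estimate is
the ratio β_D,MB = β_D,hAB / β_MB,hAB with delta-method standard error

    σ_D,MB = sqrt((σ²_D,hAB + β²_D,MB σ²_MB,hAB) / β²_MB,hAB),

Wald z-scores against N(0,1), fixed-multiplier 1.96 confidence intervals,
and Benjamini–Hochberg step-up FDR adjustment across the disease panel.

Identification requires the three IV assumptions: hAB shifts MB (relevance,
checked empirically via the stage-1 z-score); hAB shares no cause with D
(no confounding — motivates restricting to the healthier stratum, ages
23–50 with at most 5 courses); and hAB affects D only through MB
(exclusion). Regressions are unadjusted by default; age and sex can be
supplied as additive covariates (`PanelSettings.covariates`) since health
behavior may otherwise confound the instrument.

Two caveats are inherent to the design and deliberately not "fixed":

- **Scale mixing.** The numerator is a marginal log-odds slope, the
  denominator a linear slope, so the estimand is a log-odds effect of the
  marginal exposure shift. Logistic non-collapsibility attenuates the
  marginal stage-2 slope relative to the conditional generative slope by
  roughly 1/sqrt(1 + 0.35·v), where v is the residual variance of the
  linear predictor given hAB; with the default generator this is a ~4–13%
  shrinkage toward zero for |β| ≤ 0.5. Coverage checks therefore use a 90%
  pass line for nominally 95% intervals rather than asserting exactness.
- **Weak instruments.** The delta-method variance degrades as the stage-1
  z-score shrinks; the ratio of two normals has no finite variance, and
  Monte-Carlo experiments show the raw SD of the simulated ratio is
  tail-dominated already at stage-1 z ≈ 5 (empirical SD 16%+ above the
  delta SE, occasionally wildly so), while at z ≈ 20 agreement is <1%.
  A `WeakInstrumentWarning` is emitted whenever stage-1 |z| < 2
  (configurable), and a zero stage-1 slope raises an error.

## Cohort construction

- Counting window: half-open `[index − 10y, index − 6m)`; washout
  `[index − 6m, index)`. Half-open intervals avoid double counting at the
  6-month edge. Calendar offsets (`DateOffset`) are used, not fixed day
  counts.
- One prescription record = one course; same-day duplicates of the same
  ATC code are deduplicated. Subclass counts use prefixes J01CR / J01FA /
  J01MA; the washout flag always scans all J01* regardless of the chosen
  instrument, while the usage cap applies to the instrument's own count.
- Incident disease: first matching ICD-10 prefix in
  `(followup_start + gap, followup_end]`; first occurrence on or before the
  gap cutoff marks the person prevalent (excluded for that disease);
  diagnoses after the end of follow-up are ignored (right censoring). The
  default gap is 0; the 5-year gap is a sensitivity scenario guarding
  against pre-existing but undiagnosed disease feeding back onto usage.
- Ages are completed years at the index date; all bounds inclusive.
- Diseases enter the panel only with ≥ 50 incident cases in the filtered
  analysis set (configurable).

## Microbiome feature

The pseudocount is half of the single global minimum non-zero value of the
whole genus table ("observed in the data" read as one table-wide minimum,
not per genus); zeros in Prevotella or Bacteroides are replaced by it before
taking the natural log ratio. Because the pseudocount is derived from the
same table, log P/B is exactly invariant to rescaling the table by any
positive constant, so no percent-vs-proportion unit handling is needed.
The inverse-normal transform uses Φ⁻¹((r − 3/8)/(n + 1/4)) with average
ranks for ties, matching the Blom default of the reference R
implementation; a constant vector is rejected. When the INT scenario is
active the transform is applied after eligibility filtering (ranks are
taken within the analysis set actually regressed).

## Synthetic study conditions

The generator's defaults are the study conditions used throughout the
tests and the acceptance script; where no value is dictated by the design
they were fixed once at field-plausible magnitudes:

| knob | default | rationale |
| --- | --- | --- |
| n_sample1 / n_sample2 | 50,000 / 2,500 | large EHR cohort vs typical metagenomics sub-cohort |
| total 10-y course count | negative binomial, mean 3, gamma shape 3, cap 30 | long-tailed; 3–5 courses per decade is common in low-consumption European populations |
| subclass split | 0.15 / 0.15 / 0.10 / 0.60 (J01CR/J01FA/J01MA/other) | the three focal subclasses are minorities of all J01 use |
| baseline log P/B | mixture: w=(0.7, 0.3), μ=(−2, 1), σ=(1, 1), +N(0, 0.25²) noise | bimodal enterotype structure, Bacteroides-dominant mode more common |
| ab_effect | −0.3 per course (shared across classes) | cumulative shift toward Bacteroides dominance |
| washout_prob | 0.10 | fraction with a recent course, excluded by washout |
| diseases | prevalences 5–8%, causal β = −0.5, −0.3, 0 | one strong, one moderate, one null target |
| prevalent_frac | 0.02 | pre-follow-up diagnoses exercising prevalent exclusion |
| ages / sex | uniform 18–89, 60% female | adult biobank demographics |

Outcome intercepts are calibrated by root-finding so the realized incidence
matches the target prevalence given the simulated linear predictors.
Per-course subclass allocation is multinomial, which together with the
gamma-mixed Poisson total yields small positive subclass correlations; with
the default dispersion the maximum pairwise Spearman correlation is ≈0.14,
satisfying the < 0.2 independence condition without tuning. Prescription
dates are uniform day-offsets drawn strictly inside the counting window
(and, for washout violators, strictly inside the washout), so no generated
course straddles a window boundary; offsets are redrawn per person until
distinct so deduplication never collapses real courses. All randomness
derives from a single seed through per-table substreams; output is
byte-identical across runs.

Violation knobs: `confounder_strength` couples a latent N(0,1) variable to
the usage rate, log P/B and disease risk; `direct_effect` adds an
instrument→outcome path bypassing the microbiome; `feedback_strength` makes
latent pre-index disease both inflate the usage rate (extra Poisson
courses) and shift log P/B, with the diagnosis surfacing in the first five
follow-up years — which is exactly what the 5-year-gap scenario removes.

What the generator does **not** emulate: realistic ICD-10 ontologies and
comorbidity structure, dose/duration and adherence, seasonality of
prescribing, compositional read-count noise in the abundances, or
age/sex-dependent usage and risk. Passing tests therefore demonstrate the
estimator's statistical behavior under its stated assumptions, not
performance on real registry data.

## Validation sizes and numerical choices

Null calibration runs the full pipeline at n₁ = 50,000 with the 39-column
pseudo-outcome panel; the pooled nominal significance rate over 20 seeds is
mildly conservative (≈3–4% at α = 5%) because the ratio's delta-method SE
inflates the stage-2 SE by a factor involving β̂²σ²_MB — the null p-value
distribution is stochastically above uniform, never below. Parameter
recovery and CI coverage use 50 replicates at the full 50,000 / 2,500 study
size; full-size replicates were preferred over a larger replicate count
because detection power depends on n. The Monte-Carlo delta-method oracle
uses 10⁶ draws at stage-1 z = 20 (see the weak-instrument caveat above).
Cohort rules are fuzzed against pure-Python brute-force oracles on 1,000
random record sets; BH-FDR and INT are compared elementwise (atol 1e-12)
against an independent reference implementation and an independent
sort-based ranking, respectively, on 1,000 random vectors each.

Degenerate inputs: a zero-variance instrument, an all-tied INT input, an
all-zero abundance table, an empty disease list and probability grids
touching 0 or 1 all raise informative errors; perfect separation in stage 2
is detected (statsmodels' check plus a diverging-coefficient guard) and
reported as a skipped panel row rather than a spurious estimate; an empty
analysis set after filtering warns (or yields a skipped scenario row in the
grid) instead of raising.
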