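# Methods

## Decision problem and model structure

Five ePRO symptom-management strategies for patients starting chemotherapy
are compared from a health-care-sector perspective over a 26-week horizon.
Each strategy is modelled as a Markov cohort with a 1-week cycle and a
single recurrent Well state: in any week a patient may incur an unplanned
emergency-department (ED) visit and/or an unplanned hospitalization —
treated as independent parallel outcomes — and returns to Well.  Mortality
was not observed in the trial the inputs come from, so the model has no
death state.  With a sub-year horizon no discounting is applied, and costs
are expected weekly accruals, so no half-cycle correction is used.  Event
risks are constant across weeks (no post-event risk modification).

Expected weekly utilization cost per arm:

    E[c_week] = p_ed · n_ed · c_ed + p_hosp · n_hosp · LOS · c_night

The conditional multiplicities `n_ed`, `n_hosp` (events per event-week,
support ≥ 1) default to ON.  The literal one-event-per-event-week variant
(`include_visit_multiplier=false`) is implemented and flag-selectable; only
the multiplier-on computation reproduces the published 26-week totals to
about 1%, which is why it is the default.  The published conditional counts
are interpreted as per-event-week multiplicities, the reading consistent
with those totals.

The 26-week total cost adds the per-patient intervention cost.  Every
published per-patient intervention cost embeds a uniform development share
of $1,253 (the development total of $491,118 is carried as metadata; no
printed denominator reproduces the share, so it is a configuration
constant).  `include_development=false` subtracts exactly that share from
every arm, leaving the arm-specific labor component (e.g. $90 for NP-DSS).

## Effectiveness

Effectiveness is the symptom-burden score on a 0–10 scale (0 best), not a
QALY.  The daily burden of a patient is the mean severity over the 11
surveyed symptoms; weekly scores average patients' within-week means over
patients on study that week.  A quadratic S(t) = a + bt + ct² is fitted by
least squares to the weekly series (weeks indexed t = 1..26); the
effectiveness score is the horizon mean (1/T)·∫₀ᵀ S(t)dt = a + bT/2 + cT²/3,
clipped to [0, 10].  Interior missing weeks are linearly interpolated before
the fit (neutral for polynomial fitting); leading/trailing missing weeks are
left out and covered by the fitted curve.  Burden scores are deliberately
deterministic inside the cohort model and the PSA: no individual-level
variability estimates exist for them.

Because the patient-level weekly series were not published, the default
configuration encodes each arm's weekly curve as the line
S(w) = (E + 1) − w/13, whose quadratic fit integrates back exactly to the
published 26-week mean score E per arm (6.5, 6.9, 5.2, 5.3, 4.5).  Any
curve with the same horizon mean gives identical downstream results; the
declining shape only matters for the synthetic generator's realism.

## Frontier analysis

Strategies are scored internally as burden reduction against a fixed anchor
of 10 (the worst score), making ICERs anchor-invariant.  Construction:
sort by cost (ties: better effect first, then canonical arm order; an exact
tie in both marks the later strategy absolutely dominated); remove
absolutely dominated strategies (≥ cost and ≥ burden with one strict);
iteratively remove extended dominance — a strategy whose incremental ICER
is not below the next frontier strategy's — until ICERs increase strictly
along the frontier.  The least costly survivor is the reference.  The
implementation is tested against an independent brute-force oracle (a
strategy is on the frontier iff it uniquely maximizes net monetary benefit
at some willingness-to-pay) on 1,000 random instances.

## Probabilistic sensitivity analysis

Second order, K = 1000 outer draws (configurable).  Per draw, all uncertain
parameters move simultaneously and independently: weekly event
probabilities ~ beta, unit costs, conditional counts and LOS ~ gamma, all
parameterized by method of moments from the published (mean, sd) pairs.
Conditional counts and LOS keep their ≥ 1 support by placing the gamma on
the excess over 1.  Intervention and development costs have no published
dispersion and stay fixed.  The inner evaluation defaults to the closed
form — the 1000-patient microsimulation inner loop is available by flag but
only adds first-order noise around the same mean.  Probability SDs are
across-patient SDs of per-patient weekly proportions, which is why they can
exceed the binomial bound; should a configured sd be infeasible for a beta
(sd² ≥ mean(1−mean)) it is shrunk to 0.95·√(mean(1−mean)) with a logged
warning (no published row triggers this).  sd = 0 yields a point mass.

CEAC: at each λ on the grid (default $0–20,000 by $250, covering the
frontier-ICER region) a strategy's acceptability is the fraction of draws
in which it attains the maximal NMB = λ·(10 − E) − C; exact ties split
equally; no smoothing.  With effects fixed across draws, the acceptability
of the lowest-burden arm converges to 1 as λ → ∞.

## Synthetic cohort generator

The generator emulates the published trial's statistical signatures, not
its content (no coaching logic, NP call content or tracker streams):

* arm sizes 143/147/150/157/171 (the sizes accompanying the utilization
  table; the trial text's 143/144/148/155/167 differ — the table's sizes
  are used because they travel with the model inputs);
* time in study ~ truncated normal(69.6, 25.6) days on [7, 182], so most
  patients leave well before the 26-week cap, thinning late weeks exactly
  as in the trial;
* weekly events: any-ED ~ Bernoulli(p_ed); given any, count = 1 +
  Poisson(mean − 1) (support {1, 2, …}, one parameter, exact conditional
  mean); hospitalizations likewise; LOS per admission = 1 + a gamma draw on
  the excess nights discretized by stochastic rounding (floor +
  Bernoulli(fractional part)) — whole nights ≥ 1 with expectation exactly
  the configured mean, so estimator round-trips are unbiased;
* reporting adherence per patient ~ Beta(0.179, 0.135), solved so the
  median is 0.756 and the lower quartile 0.039 (the published median and
  IQR describe a U-shaped mix of near-daily and near-never reporters);
  days report independently with the patient's adherence;
* daily severities: each symptom ~ Normal(curve(week), 1.5), clipped to
  [0, 10] and rounded.  The 1.5-point day-to-day sd is a realism choice
  (no daily dispersion was published); it is small enough that clipping at
  the scale bounds does not bias arm means in the 4.5–6.9 range.

What the generator does not emulate: within-patient event correlation,
seasonal or treatment-cycle structure in symptoms, informative dropout
(events and symptom level are independent of time on study), site effects,
and any association between adherence and health status.  Passing
parameter-recovery tests therefore shows the pipeline is internally
consistent and unbiased under the published marginal structure — not that
it would be unbiased under real-world correlation patterns.

## Problem sizes and numerical checks

The test suite runs the generator→estimator round trip at 10,000 patients
per arm (recovery of every published utilization mean within 3 Monte Carlo
SEs), the cohort microsimulation at 10,000 patients against the closed form
(3 SEs), the PSA at 1000 outer draws against the base case (3 SEs), and
method-of-moments round trips to 1e-9 with 10⁶-draw sampling checks
(4 SEs).  All stochastic stages consume explicit seeds; identical
configuration and seed reproduce every output byte for byte.  The
acceptance script evaluates the deterministic model on the published
inputs, so its ICER is seed-invariant.

## Known limitations

* The published totals are not exactly recomputable: inputs are printed
  rounded, and the recomputed complete-system cost sits ≈4.5% above the
  published one (its inputs round most coarsely), placing the frontier
  ICER near the upper edge of the rounding envelope around the published
  value.
* The published PSA summary rows and the acceptability-curve threshold
  figure are internally inconsistent as printed (effectiveness values that
  contradict the held-constant rule, a threshold three orders of magnitude
  below the ICER); they are not reproduction targets.
* Utilization unit costs are consumed as printed 2023 USD; no independent
  re-estimation or re-inflation is attempted.
* Comparison is restricted to the five system components; there is no
  usual-care comparator and no QALY conversion, by design of the source
  analysis.
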