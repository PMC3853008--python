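# Methods

## Model

The US adult (20+) population is partitioned into five glycemic states —
normal glucose, IFG without IGT, IFG with IGT, undiagnosed diabetes,
diagnosed diabetes — and advanced annually by

    N(t) = N(t-1) P(t) + B(t) + M(t),

with `N` the row vector of counts (millions), `B` aging-in entrants, `M` net
migration, and `P(t)` the annual transition matrix whose rows sum to one
minus the state's death probability.  Death probabilities are a common base
rate times fixed mortality relative risks (1, 1, 1, 1.77, 2.11).  Structural
zeros encode three assumptions: no remission from diabetes; diagnosed
diabetes is absorbing except for death; and no regression between
prediabetes stages.

Flows out of the non-diabetes states are (i) diabetes incidence at annual
probabilities 0.3% / 2.4% / 3.9% (normal / IFG-only / IFG+IGT), times a
calibrated common scale, times any intervention multiplier, split between
the undiagnosed and diagnosed destinations by a diagnosed-at-onset fraction;
(ii) stage progression normal→IFG and IFG→IFG+IGT; and (iii) detection of
undiagnosed diabetes at a constant annual rate.  Because the per-state
incidence and detection probabilities are all constant in the flat-trend
configuration, the incidence-to-detection ratios are constant over time.
Probability mass removed by an intervention returns to the diagonal: people
whose incident diabetes is prevented remain in their risk stratum, at that
stratum's incidence, which is why long-horizon prevented-case counts are
much smaller than naive effectiveness × incidence arithmetic suggests.

### States, interventions, and scenario semantics

Intervention multipliers act on the incidence probabilities only (not on
detection or mortality).  The targeted strategies multiply incidence in
their target states by (1 − 0.125), the population strategy multiplies all
non-diabetes states by (1 − 0.02), and the combined strategy composes the
two: (1 − 0.125)(1 − 0.02) on IFG states, (1 − 0.02) on normal glucose.
Interventions act from the first transition (2007→2008).  The 12.5% default
is an identification × participation × efficacy cascade (0.5 × 0.5 × 0.5).

## Calibration

The published inputs fix the 2007 state mix (12.9% diabetes, 26.7% IFG of
whom 8.3% also have IGT; the diagnosed share of diabetes is taken from the
only printed split, 16.3/22.7 ≈ 0.718), the stratum incidences, and the
mortality relative risks.  Seven remaining scalars are solved jointly by
deterministic nonlinear least squares on the **no-intervention run only**:

| unknown | role | solved value (base case) |
|---|---|---|
| detection rate | undiagnosed→diagnosed per year | 0.0061 |
| diagnosed-at-onset fraction | split of incident cases | 0.722 |
| normal→IFG progression | per year | 0.0110 |
| IFG→IFG+IGT progression | per year | 0.0165 |
| effective crude death rate | overall mortality level | 0.0328 |
| migration fraction | share of entrants allocated by current mix | 0.864 |
| incidence scale | common multiplier on stratum incidence | 1.076 |

Residuals, each scaled by its stated tolerance so that one unit means "at
tolerance": prevalence counts and cumulative incident cases at the
2010/2015/2020/2025/2030 anchors (±5% relative); the diagnosed share of
diabetes at mid-horizon and 2030 (±0.02); and the IFG-only and IFG+IGT
shares of the non-diabetic population at mid-horizon and 2030 relative to
their 2007 values (±10% relative, the quasi-stationarity condition).  Total
population per year is back-derived from published count/rate pairs with
geometric interpolation between anchors and is matched exactly by
construction: each year the entrant flow is whatever the target requires
after survival, split into births (into normal glucose) and migration
(allocated proportionally to the current state mix) by the migration
fraction.  Per-year base death rates are obtained by inverting the effective
crude rate through the evolving state mix and the relative risks, then
frozen into the demographic schedule; scenario runs reuse the frozen rates
and the same population targets (census-style totals do not depend on
diabetes policy), re-deriving only the entrant split.

Three of the solved scalars deserve comment.  The *incidence scale* absorbs
a documented ambiguity in the inputs: the stated overall initial incidence
is 1.22%/yr, but the printed stratum rates weighted by the printed 2007
prevalences give 1.09%/yr; the fitted scale (1.076) puts the model's
first-year overall incidence at 1.17%/yr, inside that bracket.  The
*effective crude death rate* (3.3%/yr) is far above the demographic crude
rate for US adults (~1.1%/yr) because the model has no age structure:
diabetes is concentrated at ages with high absolute mortality, and a
homogeneous model can only reproduce the published balance of cumulative
incidence against prevalence growth by raising the overall mortality level.
The *migration fraction* is likewise effective, not demographic: entrants
allocated proportionally to the current mix are the only channel through
which prevalent diabetes enters from outside the incidence process, and the
published trajectory requires a substantial such inflow.  All three are
reported in the calibration report rather than interpreted as demographic
estimates.

The rising-incidence background scenario multiplies incidence by a constant
annual growth factor, solved (bisection) so the no-intervention 2030
prevalence rate sits 3.5 percentage points (the midpoint of the published
"three to four") above the flat-trend value; the solved factor is ≈1.9%/yr.

## Uncertainty propagation

Full Monte-Carlo over all epidemiologic inputs is out of scope; the
dominant uncertainty is intervention effectiveness, for which no data
exist.  For each strategy the model is run over a log-spaced factorial of
effectiveness values spanning half to double the base case (5 points per
active predictor), and an OLS emulator `Y = b0 + b1 ln X1 + b2 ln X2` is
fit, where `Y` is the 2030 reduction in prevalent diabetes versus no
intervention.  Fits achieve r² ≈ 0.95 on these designs.  Subjective
effectiveness distributions are lognormal with median at the base case and
2.5th/97.5th percentiles at half/double it — the same bounds the
sensitivity analysis uses; this is a package design choice, exposed in the
config.  Propagation samples the distributions, evaluates the emulator,
adds Gaussian residual noise (a prediction interval, since the emulator
approximates the model itself), and reports empirical 2.5th/97.5th
percentiles truncated below at zero (an intervention is not reported as
increasing prevalence).  Propagation is seeded and bit-reproducible.

## Synthetic data

`dmpolicy.synthetic` generates census-like inputs for testing: geometric
population growth (defaults: 215.5 M growing 0.94%/yr to 267.4 M over
2007–2030, the US back-derived totals) with multiplicative lognormal noise;
entrants consistent with the totals under a nominal 1%/yr death rate; and
multiplicatively jittered parameter sets with the stratum-incidence
ordering enforced by rejection.  The generators emulate the *aggregate*
structure the model consumes — totals, entrant flows, state shares — not
individual-level survey data, age structure, or sampling error in the
prevalence estimates; tests passing on synthetic data therefore validate
the solvers and the projection arithmetic, not the realism of any
particular epidemiologic input.  The recovery harness generates data with
known detection/onset/progression rates, runs the model forward, and
re-solves those rates from the outputs (10% relative agreement required).

## Numerical choices and edge cases

* The difference equation, calibration, and all tables are fully
  deterministic; only emulator propagation consumes a seed.
* Joint calibration uses `scipy.optimize.least_squares` (trust-region
  reflective, bounds keeping probabilities in [0,1], crude rate in
  [0.001, 0.06], scale in [0.5, 2]) from a fixed starting point; the
  single-purpose solvers (detection/onset, progressions) use the same
  machinery on their 2×2 subproblems and raise if their residuals exceed
  the stated tolerances (no solution in the unit square).
* Transition-matrix construction raises if outflows would drive a diagonal
  entry negative, or if a relative risk pushes a death probability above 1.
* A step that produces a negative count (inconsistent demography) raises
  rather than clipping.
* Population-target interpolation is geometric, so totals are positive and
  growth rates piecewise constant; identical anchors yield a constant
  series.
* The published start-year cumulative-incidence entry is offset by one
  transition relative to later anchor columns and is excluded from
  calibration; cumulative incidence here counts all transitions into
  diabetes from the start year, which coincides with the published
  convention at 2030.

## Problem sizes

The full projection is 23 annual steps over 5 states; a calibration is a
few hundred such runs (~3 s), an emulator design 3–25 runs, and propagation
10⁴–10⁵ draws by default.  The complete test suite and all analysis scripts
run in well under a minute on one CPU.

## Known limitations

No age/sex/race structure (the mortality and migration scalars are
effective parameters as a result); no cost dimension; remission and
mortality time-trends excluded by assumption; the combined strategy's
prevented-prevalent count runs ~10% above the published value — the
published prevented-prevalent/prevented-incident ratio depends on the
unpublished health mix of migrants and on rounding in the printed rates,
and the calibration deliberately never fits scenario outputs.
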