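# Methods

## The model

The package analyses a two-alternative perceptual task (is the dominant
colour of a briefly shown square orange or blue?) in which, during a fixed
deliberation phase, the participant may see the choice of a previous
participant (the social information, SI) either early or late, and then
reports a single judgment on an 11-point confidence scale from "100%
orange" through "50%" to "100% blue".

The cognitive model treats the subjective evidence state at judgment time
as a diffusion read out once, on an axis whose positive direction is the
*correct* option:

    E[L_c]   = tau * col + delta_p * DT + (delta_s * ST + gamma) * lambda
    var[L_c] = sigma * DT,   sigma = 1 (scale convention)

- `DT` (s): time from stimulus onset to judgment = 1 s stimulus display
  + deliberation phase + response latency.
- `ST` (s): time from SI onset to judgment = (deliberation − SI onset)
  + response latency; zero when no SI is shown. The social drift runs from
  cue onset to judgment regardless of how long the cue stays visible, so
  the same model covers both display-duration regimes.
- `col` = +1 orange dominant / −1 blue; `lambda` = +1 correct / −1 wrong SI.
- `delta_p` (evidence/s): personal drift, `delta_easy` or `delta_hard` by
  stimulus difficulty; `delta_s` (evidence/s): social drift; `gamma`
  (evidence): instantaneous social shift; `tau` (evidence): colour bias
  toward orange.

Ten criteria `c_1 < ... < c_10`, mirror-symmetric about zero
(`c_k = −c_{11−k}`, parameterized as five positive increments), cut the
evidence axis into the 11 confidence categories; each category's
probability is the normal mass between its criteria. The model predicts
confidence judgments only, never response times — judgments are prompted
at a fixed moment, so first-passage machinery would be misspecified.

The two social mechanisms make distinct timing predictions: a pure shift
(`delta_s = 0`) implies identical predicted judgment distributions for
early and late SI at matched `DT`, while a drift (`delta_s > 0`) implies an
early-minus-late difference in mean evidence of exactly
`delta_s * (ST_early − ST_late)`. These closed forms are asserted verbatim
in the test suite.

On trials without social information the social terms are multiplied by
zero — the minimal extension of the SI-present equation to the no-social
and filler treatments. Filler trials never enter any analysis.

## Hierarchical fitting

Subject-level `delta_easy, delta_hard, delta_s, gamma, tau` are normal
around population means; the criteria increments are shared across
subjects. Priors (nothing in the problem dictates them, so they are weakly
informative and overridable): N(0, 2²) on population means, half-normal(1)
on population spreads and on criteria increments. Criteria ordering is
enforced by construction (positive increments), not by rejection.

Posterior sampling is a blocked adaptive Metropolis-within-Gibbs scheme
written for this likelihood:

- per-subject random-walk updates of the (up to five) free parameters,
  preconditioned per dimension by the Gaussian-equivalent Fisher
  information plus the current population precision;
- conjugate normal draws for population means;
- near-conjugate inverse-gamma independence proposals for population
  spreads (only the half-normal prior ratio enters the acceptance);
- an interweaved non-centred move rescaling all subjects around the mean
  with z-scores fixed, repeated for prior-dominated parameters — this
  breaks the funnel that makes centred samplers crawl when a spread is
  small relative to the per-subject likelihood information;
- a joint 5-dimensional random walk on the log criteria increments;
- a "ridge" move shifting every subject's `delta_s` (and its population
  mean) by `d` while compensating `gamma` by `−d · mean(ST)`: the two
  social parameters are nearly collinear (the shift can absorb the drift's
  average effect; only the early/late contrast separates them), and this
  move explores that direction orders of magnitude faster than coordinate
  updates.

Proposal scales adapt during burn-in only (Robbins–Monro); chains are
seeded independently from one `SeedSequence`, so every fit is bit
reproducible. Each chain starts from a penalized pooled-likelihood optimum
(all subjects sharing one parameter vector), which removes most burn-in
transient. Convergence is reported as split-R̂ and bulk ESS (arviz) for
every stored population-level quantity; a fit exceeding the configured
tolerance is returned flagged, never silently. The spread of `delta_s` is
the slowest-mixing quantity — its subject-level values are essentially
prior-driven at 100 trials per subject — and at the reduced budgets below
its R̂ sits in the 1.1–1.25 range while all population means are at ≤1.01;
the full budget (5 chains × 5000 iterations, half burn-in, R̂ ≤ 1.01
tolerance) is available as `full_budget()`.

Model comparison fits the eight variants obtained by toggling personal
drift, social drift and social shift (`tau` and the criteria are always
estimated) on the same data and ranks them by LOOIC = −2·elpd_loo from
PSIS-smoothed leave-one-out (arviz) on the stored pointwise
log-likelihood matrix; points with Pareto k > 0.7 are counted and
reported, and if PSIS fails outright the code falls back to WAIC with a
warning. Failed or non-converged fits are ranked last and flagged.

Evidence ratios for directional hypotheses are the count of posterior
draws in the hypothesized direction over the count against, capped at the
number of draws when no draw opposes; 1–3.2 is read as weak, 3.2–20 as
substantial, >20 as strong evidence.

## Signal-detection analyses

The ordered-probit regression treats the 11-point judgment as an ordinal
response cut from a latent unit-variance normal. The stimulus is coded
`s = col/2`, so the coefficient on `s` *is* d′, and the five-level SI
condition (absent / early-correct / late-correct / early-wrong /
late-wrong), a hard-stimulus indicator and the z-scored trial number enter
only in interaction with `s`, i.e. as Δd′ — condition main effects
(criterion shifts) are deliberately off by default, matching the
discrimination-ability framing. Ten free (asymmetric) thresholds are
shared across subjects; subjects contribute normal random intercepts on
the latent scale. The companion binary probit models correctness on SI
validity (or presence), difficulty, colour and trial number with the same
random-intercept structure.

Both fits use the same sampler contract as the accumulator: a joint
coefficients-plus-thresholds block whose proposal is shaped by the inverse
Hessian at the pooled penalized optimum (a Laplace preconditioner),
per-subject intercept updates, and the near-conjugate spread draw.

Contrasts reported: each Δd′ against zero, early−late within correct and
within wrong SI, |correct|−|wrong| per timing, and the timing-symmetry
contrast `(early−late)_correct − |(early−late)_wrong|`, each with a 95%
interval and a directional evidence ratio.

## The synthetic-data generator

`PopulationSpec.experiment1()` / `.experiment2()` define the default study
conditions: 120 trials in 20 blocks of six (2 early-SI, 2 late-SI, 1
no-social, 1 filler per block, shuffled within block), SI onsets 750 or
3250 ms into a 4000 ms deliberation with continuous ±250 ms uniform
jitter, 70% SI accuracy by construction (28 correct vs 12 wrong trials per
timing), difficulty × colour exactly balanced within every treatment, and
filler trials with a 1000 ms deliberation. Experiment 2 differs only in
the 500 ms cue display and the 3 s (instead of 2 s) response window.

Population means sit at the reported point estimates (experiment 1:
`delta_easy` 0.90, `delta_hard` 0.60, `delta_s` 0.18, `gamma` 2.41, `tau`
0; experiment 2: 0.81 / 0.55 / 0.14 / 2.06 / 0); `delta_hard` is not
printed anywhere and is set to roughly two-thirds of the easy drift.
Population spreads are this package's choice: 0.15 for the personal
drifts, 0.06 for `delta_s`, 0.75 for `gamma`, 0.30 for `tau` — substantial
heterogeneity in social uptake, consistent with both social processes
being present in a large majority (not all) of subjects.

Criteria default to increments (0.875, 1.75, 1.75, 1.75, 1.75), i.e.
criteria about 1.75 evidence units apart.

Response latencies are log-normal, truncated to (0, response window + 1 s);
the location is calibrated (by root finding on the truncated-conditional
mean) so that *analysed* (on-time) latencies average 1.1 s in experiment 1
and 1.3 s in experiment 2, which puts the mean judgment 3.1 s / 3.3 s
after SI onset. With log-sd 0.4 / 0.5 the natural tail yields ≈5% / ≈3%
late responses, matching the regimes the exclusion rules expect; an
`extra_late_probability` knob can force more. Latencies are independent of
the evidence state — the generator does not model the empirical
correlation between difficulty and response speed, nor any sequential
dependence across trials, so passing tests say nothing about such effects
in real data.

A pathology injector rewrites named subjects into the four exclusion
archetypes (always-100% responder, below-chance responder, chronic late
responder, miscalibrated-confidence responder) and returns ground-truth
labels, making the exclusion rules self-verifying.

Known limitation of point-estimate emulation: with `delta_easy = 0.90` and
`DT ≈ 6 s`, the model puts easy/no-SI accuracy near ceiling (~99%), well
above the ~69% the task produces empirically — the printed population
means and the printed raw accuracies are not jointly reproducible inside
this model, and the generator follows the parameters. All recovery and
ordering checks are unaffected (they compare signs, orderings and
generating-vs-recovered values), but two consequences are worth knowing:
absolute d′ values from synthetic data are larger than empirical ones, and
the binary-probit SI-*presence* effect turns negative in the synthetic
world (at ceiling, wrong SI costs more than correct SI can add), whereas
the empirical study reports a small positive presence effect.

## Preprocessing conventions

Points per judgment: `100·[1 − (correct − conf)²] − 75` with confidence on
the grid .50–1.00; the bonus is $0.2 per 100 points with a $1 floor that
binds exactly below 500 points. Subject exclusions: >90% of trials at
100% confidence; mean accuracy below 50%; more than 10 late responses;
mean confidence higher on wrong than on correct trials (strict
inequality, ties keep the subject; undefined when a subject has no wrong
or no correct trials); an optional pass-through glitch flag. Neutral (50%)
responses count in the full-confidence denominator and late counts but not
in accuracy; all trials including fillers enter the counts (whether the
late-response rule counts fillers is ambiguous in the source design; this
package counts them). Trial filters per analysis: accuracy drops neutral
responses and fillers; accumulation drops late responses and fillers;
ordinal drops fillers only. Filters are idempotent.

## Problem sizes and numerical choices

Simulation studies in the tests and the acceptance script run at reduced,
fixed scales chosen as this package's standard desk-scale studies:
parameter recovery at 30 subjects × 120-trial schedules (≈95 analysed
trials each) with 3 chains × 1500 iterations; the eight-way model
recovery at 24 subjects with 3 × 600 iterations per variant; shift-vs-drift
discrimination at 10 subjects; ordered-probit recovery at 10 subjects ×
100 trials with 3 × 1200 iterations. Zero-probability cells in the
likelihood are floored at 1e-300 and counted (`n_floored`), so pathological
parameter regions degrade diagnostics loudly instead of crashing. The
Monte-Carlo oracle checks use 1e5 draws per condition and 3-binomial-SE
bands. Degenerate inputs (constant trial numbers, single-class responses,
single subjects, non-positive DT, unordered criteria) are rejected with
explicit messages.
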