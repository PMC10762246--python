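# socialdrift

Does social information sway a perceptual judgment more when it arrives
earlier? `socialdrift` implements the full analysis pipeline for answering
that question in a two-alternative colour-discrimination task with an
11-point confidence scale, where the choice of a previous participant (the
social information) appears either early or late in a fixed deliberation
phase.

Two cognitive mechanisms are distinguished. An *instantaneous shift*
updates the evidence state once, so timing should not matter; a *social
drift* integrates the cue continuously, so earlier cues should weigh more.
The core model captures both: at judgment time the evidence `L_c` on the
correctness axis is normal with

```
E[L_c]   = τ·col + δ_p·DT + (δ_s·ST + γ)·λ
var[L_c] = σ·DT          (σ = 1)
```

where `δ_p` is the personal drift (by stimulus difficulty), `δ_s` the
social drift accruing over the time `ST` since cue onset, `γ` the shift,
`τ` a colour bias, `col` the dominant colour (±1) and `λ` the cue's
validity (±1). Ten mirror-symmetric criteria cut the axis into the 11
confidence categories, giving a closed-form ordered likelihood (no
response-time modelling). Shift-only ⇒ identical early/late predictions;
with drift the early−late gap in mean evidence is exactly `δ_s·ΔST`.

The package provides:

- **`design`** — generation and validation of the 120-trial, six-treatment
  within-subject schedules (70% cue accuracy by construction, ±250 ms
  onset jitter, both display-duration regimes);
- **`synthetic`** — a full generative emulation of the experiments:
  population-distributed subject parameters, judgments from the model,
  calibrated truncated log-normal latencies, and injectable pathological
  subjects for testing the exclusion rules;
- **`preprocessing`** — the Brier-based scoring rule and bonus formula,
  subject exclusion criteria, per-analysis trial filters, accuracy
  summaries;
- **`accumulator`** — the likelihood, hierarchical Bayesian fitting
  (blocked adaptive Metropolis-within-Gibbs, written for this posterior),
  the eight-variant comparison by PSIS-LOO (LOOIC), evidence ratios and
  parameter-recovery studies;
- **`sdt`** — ordered-probit signal detection (the stimulus coefficient is
  d′, condition effects are Δd′), directional contrasts with evidence
  ratios, binary probit accuracy models, posterior predictive confidence
  distributions;
- **`pipeline` / CLI** — an end-to-end, fully seeded run with a text
  report.

## Worked example

```python
from socialdrift import (
    DesignConfig, PopulationSpec, ModelVariant, SamplerConfig,
    apply_trial_filters, fit_hierarchical, compute_looic, simulate_experiment,
)

pop = PopulationSpec.experiment1(n_subjects=10)      # defaults emulate study 1
sim = simulate_experiment(pop, DesignConfig(experiment=1, seed=3), seed=7)
data = apply_trial_filters(sim.dataset, "accumulation")   # drop late + filler

fit = fit_hierarchical(data, ModelVariant(),              # full mechanism
                       SamplerConfig(n_chains=3, n_iter=900, n_burn=450, seed=1,
                                     rhat_tol=1.2))
for name in ("delta_easy", "delta_s", "gamma"):
    d = fit.population_draws(name)
    print(name, round(d.mean(), 2))
print("LOOIC", round(compute_looic(fit).looic, 1))
```

prints (this exact run):

```
delta_easy 0.92
delta_s 0.13
gamma 2.29
LOOIC 2739.0
```

The population means land on the generating values (0.90, 0.18, 2.41 with
10 subjects' worth of uncertainty), and the LOOIC is the deviance-scale
out-of-sample score used to rank model variants — `compare_variants`
repeats this across all eight shift/drift combinations and, on data like
these, selects the full model, mirroring the conclusion that social
information acts through *both* an immediate update and continuous
integration.

There is also a CLI: `socialdrift simulate|preprocess|fit-accumulator|
compare-models|recover|fit-sdt|report|run-all` (see `--help`).

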