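# Methods

## Model

All estimators assume a parallel-group randomized trial with
independent arms and an additive decomposition of each subject's
improvement:

```
improvement = non_specific + contextual · exposure(arm) + specific · 1[active] + ε
```

- *non-specific* improvement (natural course, regression to the mean,
  measurement error) accrues to every arm;
- the *contextual* component accrues in proportion to the arm's
  contextual exposure (blinded placebo and active arms: 1; untreated
  control: 0; open-label placebo: a configurable fraction);
- the *specific* component accrues only to the active arm;
- ε is mean-zero noise.

No interaction between components is modeled; the additive model is
adopted deliberately, as the simplest model under which the group
contrasts below identify their targets. Crossover designs,
individual-patient meta-analysis, and non-additive models are out of
scope.

## Estimators

**Improvement orientation.** All changes are oriented so that positive
means better: `mean_baseline − mean_followup` on lower-is-better
scales, the reverse otherwise.

**Within-arm change.** `mean_change` has SE `sd_change/√n`. When only
baseline and follow-up SDs are reported, the change SD is imputed as
`√(sd_b² + sd_f² − 2 r sd_b sd_f)` with pre/post correlation
`r = 0.5` by default (overridable per arm or per call); `r` affects
SEs only, never point estimates.

**Standardized mean change** `d = Δ/SD` supports three standardizers
(`sd_basis`): baseline SD (default), follow-up SD, or change SD. The
source method for the PCE ratio never states which SD standardizes the
change, so the choice is exposed rather than guessed. Large-sample
variance: `2(1−r)/n + d²/(2n)` for baseline/follow-up standardization,
`1/n + d²/(2n)` for change-SD standardization.

**Between-arm contrasts.** `mean_difference_between` contrasts
improvements (default) or oriented follow-up levels, with
`SE = √(se_a² + se_b²)` (independent arms). `smd_between` divides by
the pooled SD of the chosen scores, with variance
`(n_a+n_b)/(n_a n_b) + d²/(2(n_a+n_b))` and optional small-sample
factor `J = 1 − 3/(4·df − 1)`, `df = n_a + n_b − 2`.

**Contextual effect** = placebo vs no-treatment contrast: non-specific
improvement cancels. The open-label variant (blinded placebo vs
open-label placebo) estimates only the contextual increment due to
believed active treatment — a lower bound on the full contextual
effect, since whatever context the open-label arm retains cancels too.

**Three-arm decomposition**: total = active improvement; non-specific
= no-treatment improvement; contextual = placebo − no-treatment;
specific = active − placebo. The point estimates satisfy
`specific + contextual + non_specific = total` — exactly in algebra,
up to IEEE round-off (≲1e−12 on unit-scale values) in floating point,
which is the tolerance the tests use. When a study has both a blinded
and an open-label placebo arm, the blinded arm feeds the decomposition
by default. A descriptive `contextual/total` share (defined only for
positive totals, with a within-arm percentile bootstrap CI from
subject-level data) is offered as an exploratory summary; it is a
plain additive share, not the PCE ratio.

**Responder analysis** counts subjects with improvement ≥ threshold
(ties count as response) with a Wilson score CI. It is implemented so
its flaw is demonstrable: in a placebo arm the proportion equals
Φ(ns/σ) even with zero contextual effect.

## The PCE pipeline (reproduced, not endorsed)

Per study: `PCE = d_placebo/d_active`; `ln PCE = ln d_placebo − ln
d_active`; SE of the log from the response-ratio (ratio-of-means)
variance applied to the raw mean changes,

```
SE² = s_p²/(n_p Δ_p²) + s_a²/(n_a Δ_a²)
```

with `s` the change SD — the standardizing SDs cancel in the ratio
when both arms share the `sd_basis`. The exact SE formula used by the
original proponents is not published alongside the method; this
response-ratio variance is the documented interpretation. Studies with
`d ≤ 0` in either arm are marked excluded ("worsening or zero change";
the boundary `d = 0` is excluded because its log is undefined).
Retained log values are pooled (DerSimonian–Laird by default) and the
summary exponentiated. Values above 1 are reported raw and flagged,
never truncated — truncation would hide the pathology the module
exists to expose. The ratio-of-ratio-of-means repair for change scores
is noted as out of scope.

Known behaviors demonstrated in the tests: the log-law identity (the
ratio is a between-group treatment contrast), reciprocity, confounding
by the standardizing SD (scaling one arm's SD by λ scales the ratio by
1/λ), conflation of non-specific effects (expected PCE ≈
(ns+c)/(ns+c+s) under equal arm SDs, hence ns/(ns+s) > 0 even when
c = 0), and upward distortion from the exclusion rule under small mean
changes and large noise.

## Meta-analysis

Inverse-variance pooling of `(y, v)` pairs. Fixed effect:
`μ̂ = Σ(y/v)/Σ(1/v)`, `SE = 1/√Σ(1/v)`, `Q = Σ w (y − μ̂)²`. Random
effects: DerSimonian–Laird moments `τ̂² = max(0, (Q − (k−1))/C)`,
`C = Σw − Σw²/Σw`, weights `1/(v + τ²)`;
`I² = max(0, (Q−(k−1))/Q)·100`. Only the DL estimator is provided, to
keep the audit surface small; CIs are normal-theory Wald
(Knapp–Hartung out of scope). With `k = 1`, random-effects pooling
returns the single study with a logged warning rather than erroring,
so single-study pipelines degrade gracefully.

## Simulator

`simulate_study` draws study-level components
`(ns_k, c_k, s_k) ~ Normal((ns, c, s), (τ_ns², τ_c², τ_s²))`, then per
subject `baseline ~ Normal(baseline_mean, baseline_sd²)` and
improvement per the additive model with `ε ~ Normal(0, σ²)`;
`followup = baseline − improvement` (outcomes are fixed to
lower-is-better, pain-scale convention; orientation conversions live
in `effects`). Defaults: n = 100/arm, baseline 60 ± 20 on a 0–100
scale, ns = 0.5, c = 0.8, s = 1.2, σ = 1 — a realistic pain-trial
regime in which the contextual effect is modest relative to noise.
Arm summaries are recomputed exactly from retained subject records,
with the empirical change SD attached.

Attrition is a logistic selection model: subject drop probability
`expit(logit(p_arm) + β·(−improvement))`, so β > 0 makes poor
improvers likelier to drop — the mechanism by which completer-based
contrasts underestimate the contextual effect when the untreated arm
suffers differential attrition. The named mechanism is selection on
outcome; "response bias" (reporting shifts without true change) is a
possible extension, not implemented.

Seeding: each study uses an independent stream keyed by
`(seed, study_index, purpose)`, so enlarging a meta-dataset never
reshuffles earlier studies and identical configurations are
byte-reproducible.

What the simulator does *not* emulate: skewed or bounded outcome
distributions (improvements can exceed scale bounds), baseline-
dependent treatment effects, non-additive interactions, measurement
models for response bias, and binary outcomes. Passing tests therefore
show estimator correctness *under the additive Gaussian model*, not
robustness to those features of real data.

## Numerical and design choices

- CI level 95% with normal quantiles throughout, configurable.
- Default pre/post correlation 0.5; default `sd_basis` baseline.
- Open-label placebo contextual exposure defaults to 0.5
  (configurable 0–1): the design's proponents state only that the arm
  is told its treatment is inert, not how much contextual effect
  survives that disclosure.
- Role synonyms in CSV input ("sham" → placebo, "waitlist"/"untreated"
  → no_treatment, "intervention" → active); missing `direction` column
  defaults to lower-is-better with a logged warning.
- Noise-free simulations produce exactly-zero change SDs; summaries
  substitute 1e−12 so downstream SEs remain defined.
- Conservation and log-law identities are asserted to 1e−12 absolute
  (floating round-off); oracle-agreement checks to 1e−10.
- Problem sizes in the test suite (e.g. 1000 replicates of
  200-per-arm studies for recovery/coverage; k = 50 and k = 100
  meta-datasets for the conflation and exclusion demonstrations) were
  chosen so Monte-Carlo error is small relative to the effects being
  demonstrated while the whole suite runs in well under a minute.

## Limitations

- Arm independence is assumed for all SEs; cluster-randomized and
  crossover designs are unsupported.
- The change-SD imputation from `r` is the only missing-data handling;
  SDs are never reconstructed from CIs or p-values.
- The PCE module reproduces the criticized pipeline as documented; any
  deviation of the original authors' unpublished computational details
  from this reading would change per-study SEs but not the ratio
  itself.
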