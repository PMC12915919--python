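# Methods

This note documents the statistical machinery of `tamvi-norms`: the models,
their assumptions, the numerical choices, what the synthetic generator does
and does not emulate, and the design decisions that were genuinely open.

## Item response models

Each TAMV-I trial yields 12 dichotomous item scores per child. Two
unidimensional IRT models are fitted per trial:

- **Rasch (1PL)** — `logit P(X_i = 1 | z) = β_i + βz`: one ease parameter
  per item plus a single discrimination shared by all items (13 free
  parameters).
- **2PL** — `P(X_i = 1 | θ) = 1/(1 + exp(−a_i(θ − b_i)))`: per-item
  discrimination `a_i` and difficulty `b_i` (24 free parameters).

Both are estimated by marginal maximum likelihood with a Bock–Aitkin EM
algorithm. The latent ability has a fixed N(0, 1) prior, which identifies
the scale (item parameters absorb location and spread). The E-step computes
posterior weights over Gauss–Hermite quadrature nodes (21 by default,
configurable); response patterns are collapsed to unique rows first. The
M-step solves the collapsed weighted logistic likelihood by Newton
iterations with step-halving — per item for the 2PL, jointly over the 13
Rasch parameters. EM stops when the relative log-likelihood change falls
below 1e−6 (500 iterations maximum).

Internally items are parameterized slope/intercept; difficulty is reported
as `b = −intercept/slope`. Estimation is **unpenalized**: items answered
(nearly) identically by everyone drive `|b|` arbitrarily large or `a`
toward 0 or very large values. Such items are flagged with warnings rather
than clipped — real calibrations of easy recognition items show exactly
this behaviour, and masking it would misrepresent the item. An EM fit is
always returned, with `converged` and per-item boundary flags.

Model choice: the likelihood-ratio test (df = 24 − 13 = 11) at α = 0.001 is
the primary criterion; BIC (`−2·loglik + k·ln n`) is always reported
alongside. The two can disagree — BIC's heavier parameter penalty sometimes
prefers the Rasch model where the LRT is decisive — so `compare_models`
returns both verdicts and never silently reconciles them.

Quadrature accuracy: for well-conditioned banks (slopes ≲ 1.5, difficulties
within ±1.5) the 21-node marginal log-likelihood agrees with a 61-node
evaluation of the same parameters to well under 0.01 at n = 1,000. Banks
combining large slopes with off-center difficulties can show errors a few
times larger; `loglik_at` lets users check any fit at a higher resolution.

## Ability scoring

`score_ability` maps a 12-item pattern plus a calibrated bank to θ:

- **modal** (default): maximizer of the N(0,1)-prior log posterior. The
  posterior is strictly log-concave (prior curvature −1 plus a negative
  semi-definite likelihood term), so Newton iteration from 0 converges
  globally; the SE is the curvature standard error at the mode.
- **eap**: posterior mean over the same Gauss–Hermite node set as the
  fitting engine; the SE is the posterior SD.

The prior keeps all-correct and all-incorrect patterns finite. Both methods
are serialized with results so any downstream norm states which was used;
modal is the default as the usual empirical-Bayes default of standard IRT
software, but nothing downstream depends on the choice. Items calibrated
with `a < 0` are used as-is; for them, answering correctly *lowers* θ — a
documented property, not a bug.

With 12 items of slope ≈ 1, test information near the center is ≈ 2.5–3,
i.e. score reliability ≈ 0.7; EAP scores then correlate ≈ 0.83 with the
generating abilities. This is an information ceiling of the instrument
length, not an estimation deficiency.

## Mixed model

The six θ scores of one child are correlated; they are modeled jointly as

    θ_ij = β₀ + b_0i + x_ij'β + ε_ij,   b_0i ~ N(0, σ_b0²),  ε_ij ~ N(0, σ_ε²)

with a participant random intercept only (no random slopes). Fitting is
delegated to `statsmodels.MixedLM`; REML is the default criterion for
reported fits. Boundary fits (σ_b0 → 0) are returned flagged, with an
optimizer fall-through (lbfgs → powell → Nelder–Mead) because the default
optimizer can return a degenerate likelihood there.

**Fixed-effect design.** Covariates enter as:

- age: a degree-2 **orthonormal polynomial basis** computed from the
  estimation sample (unit-norm columns over the long-format rows, classical
  three-term recurrence). The recurrence coefficients are stored on every
  fit, so the identical basis is evaluable for a new child — this is what
  makes out-of-sample prediction (and hence norming) well defined. Note
  that coefficients on unit-norm columns scale with √n; they are
  interpretable only together with the stored basis.
- parental education: ln(MPE + 1);
- trial: five indicators vs Trial 1; sex: girl vs boy; country: Ecuador,
  Honduras, Spain vs Colombia (reference levels chosen so the reference
  cell is Trial 1 / boy / Colombia);
- interactions: any second-order product among these terms, with the
  quadratic age column treated as its own term (`age:age2` excluded).

**Selection.** `sequential_replacement_select` searches term sets by
ML-based BIC (REML objectives are not comparable across fixed-effect sets,
so selection always refits under ML and the final model is refitted under
REML). Moves are scanned in a fixed, documented order — adds, then drops,
then swaps; main effects before interactions, interactions alphabetically —
and the first BIC-improving move is taken; the search stops when a full
scan yields nothing. Marginality is enforced: an interaction requires its
main effects, `age2` requires `age`, and a quadratic interaction requires
the linear one. The move log is returned in full. BIC counts fixed effects
plus the two variance components against `ln(n_obs)`.

**Prediction.** `predict_expected` is fixed-effects-only: a new child's
random intercept has expectation zero. Ages outside the basis's fitted
range warn (extrapolation) but do not error.

## Norming

    z  = (θ_obs − θ̂) / σ_ε
    PR = 100 · Φ(z)

The denominator is the **residual SD alone**, not √(σ_b0² + σ_ε²). This is
a substantive choice: the percentile answers "where does this single-trial
score fall among children with the same demographic profile", conditioning
on the profile-level expectation; the published worked example
(θ_obs = −0.274, θ̂ = 0.311, σ_ε = 0.571 → cumulative probability 0.153) is
reproduced exactly only under this convention. Percentiles are reported to
one decimal by default; full precision is retained in `NormResult`.

## Synthetic cohort generator

The generator reproduces the study conditions so the pipeline is testable
without the original data:

- **Demographics**: 32 strata (4 countries × 4 age bands × 2 sexes) with
  the study's exact counts (1,640 children in total; e.g. Colombia 6–8 =
  121, of whom 63 girls). Ages are whole years uniform within band — the
  published band means/SDs (e.g. 7.0 ± 0.8) match a discrete uniform, not a
  continuous one. MPE is truncated-normal (floor 0) at each stratum's
  published mean/SD. Strata are treated independently; any real MPE–age or
  MPE–sex correlation beyond the stratum summaries is not emulated.
- **Abilities**: drawn from the mixed model above with the study's final
  coefficient table as default fixed effects, σ_ε = 0.571 and σ_b0 = 0.4
  (the random-intercept SD is not published; 0.4 is a realistic value of
  the same order as the residual SD, fixed once). Zero SDs are allowed and
  give the deterministic noise-free limit.
- **Responses**: Bernoulli draws from the 2PL curves. The six true item
  banks are not published in full; the defaults anchor every printed
  (trial, word) parameter — Nariz's negative Trial-1 slope, Ojo's 3.20
  recognition slope, Sillón hardest everywhere — and fill the remaining
  items with moderate values following the published gradient
  (discrimination rising across trials, items easing with learning). The
  two most extreme published difficulties (b = 72.61 and −267.27, artifacts
  of near-zero slopes) are represented by milder stand-ins (b = 8, −40) so
  the default generative model remains usable for recovery studies.
- Only the 12 scored target words are simulated; recognition-distractor
  words are not (they do not enter scoring).

One global seed expands into per-stage child seeds (demographics,
abilities, responses), so stages re-run independently and the whole cohort
is bitwise reproducible.

Because the generator *is* the model the pipeline assumes, passing recovery
tests demonstrates internal correctness — that estimation inverts
generation — not robustness to real-data violations (local dependence
between recall trials' items, non-normal abilities, DIF across countries,
MPE measurement error). Those are outside this package's scope.

## Problem sizes and numerical tolerances

- IRT recovery studies: n = 1,500–2,000 persons, where 2PL difficulty RMSE
  is ≈ 0.06 and slope/difficulty correlations exceed 0.9/0.97.
- Mixed-model recovery: the full 1,640 × 6 cohort.
- Null-selection replicates run at quarter-scale strata (~420 children ×
  6 trials, 50 replicates): the BIC-consistency property under test is
  size-free, and the smaller cohorts keep the replicate study quick.
- EM: relative tolerance 1e−6, ≤ 500 iterations; M-step Newton: ≤ 25
  iterations, 30 step-halvings; scoring Newton: |step| < 1e−12.
- Model JSON files carry `schema_version` and full-precision floats;
  readers reject unknown versions and family tags.

## Known limitations

- No 3PL/guessing model, multidimensional IRT, or DIF analysis.
- No random slopes and no heteroscedastic residuals in the mixed model.
- Continuous norming is purely model-based; no monotonization or smoothing
  across ages is applied on top of the regression.
- Printed t/p-values for mixed-model coefficients are not produced; the
  denominator-df convention of the original analysis software is not
  replicated.
- Wald SEs from REML ignore variance-component uncertainty (negligible at
  1,640 groups, noticeable in very small cohorts).
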