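# tamvi-norms

Continuous, demographically adjusted norms for the **TAMV-I** (Test de
Aprendizaje y Memoria Verbal Infantil), a Spanish-language verbal learning
and memory test for children aged 6–17. The test presents a 12-word list
(clothing, furniture, body parts) over four free-recall trials, one delayed
recall and one recognition trial; each trial is scored word-by-word as
correct/incorrect.

The package is written for psychometricians and neuropsychologists who need
to (re)derive norms of this kind, and for clinicians who want to convert a
child's item responses into an adjusted percentile. It implements the full
pipeline:

1. **Item calibration** (`tamvi_norms.irt`). Per trial, the 12 dichotomous
   items are calibrated under the Rasch model,
   `logit P(X_i = 1 | z) = β_i + βz`, and the two-parameter logistic (2PL)
   model, `P(X_i = 1 | θ) = 1 / (1 + exp(−a_i(θ − b_i)))`, by marginal
   maximum likelihood (Bock–Aitkin EM over Gauss–Hermite quadrature, N(0,1)
   ability prior). The nested models are compared by an 11-df likelihood
   ratio test and by BIC, reported separately.
2. **Ability scoring** (`tamvi_norms.scoring`). Each child's per-trial
   response pattern is converted to a latent ability θ, either as the
   posterior mode ("modal") or posterior mean ("eap") under the standard
   normal prior.
3. **Demographic modeling** (`tamvi_norms.mixed_model`). The six correlated
   θ scores per child are modeled jointly with a random-intercept linear
   mixed model, `θ_ij = β₀ + b_0i + x_ij'β + ε_ij`, with fixed effects built
   from an orthonormal quadratic age basis, ln(MPE + 1) (MPE = mean parental
   years of education), trial, sex, country, and second-order interactions.
   Terms can be chosen by BIC-guided sequential replacement selection.
4. **Norming** (`tamvi_norms.norming`). An observed θ is located among
   demographically matched peers via `z = (θ_obs − θ̂)/σ_ε` and
   `PR = 100·Φ(z)`, where θ̂ is the fixed-effects prediction and σ_ε the
   model's residual SD.
5. **Synthetic cohorts** (`tamvi_norms.synthetic`). A generator reproduces
   the study's sampling design (1,640 children across Colombia, Ecuador,
   Honduras and Spain, stratified by country × age band × sex), draws
   abilities from the mixed model and responses from the 2PL curves — so
   every stage can be tested end-to-end and parameter recovery quantified.

## Worked example

A 17-year-old girl from Spain (parents with 18 years of education on
average) answers the recognition trial correctly on every word except the
first. Her scored ability is θ_obs = −0.274; the mixed model expects
θ̂ = 0.311 for her demographic profile, with residual SD σ_ε = 0.571:

```python
from tamvi_norms import percentile_rank

r = percentile_rank(-0.274, 0.311, 0.571)
print(f"z = {r.z:.4f}")
print(f"cumulative probability = {r.cumulative_prob:.4f}")
print(f"percentile = {r.percentile:.1f}")
```

```
z = -1.0245
cumulative probability = 0.1528
percentile = 15.3
```

She scored higher than about 15% of peers matched on age, sex, country and
parental education — a below-average but not clinically alarming result.

Calibrating items on a synthetic cohort (quarter-scale strata, ~400
children) and comparing the models:

```python
from tamvi_norms import CohortConfig, simulate_cohort, fit_rasch, fit_2pl, compare_models
from tamvi_norms.synthetic import scaled_strata, WORDS

cfg = CohortConfig(strata=scaled_strata(0.25), seed=7)
dataset, truth = simulate_cohort(cfg)
mat, _ = dataset.response_matrix(4)
fr = fit_rasch(mat, labels=WORDS, trial=4)
f2 = fit_2pl(mat, labels=WORDS, trial=4)
cmp_ = compare_models(fr, f2)
print(f"BIC  Rasch {fr.bic:.2f}   2PL {f2.bic:.2f}")
print(f"LRT = {cmp_.lrt_stat:.2f} (df = {cmp_.df}, p = {cmp_.p_value:.2e}) -> {cmp_.preferred}")
```

```
BIC  Rasch 4997.98   2PL 5034.27
LRT = 30.24 (df = 11, p = 1.45e-03) -> rasch
```

(At this reduced sample size the 11 extra discrimination parameters are not
supported by either criterion at α = 0.001 — item-level differences need the
full cohort to become detectable, which is exactly why the BIC/LRT
comparison is reported per trial.)

## Command line

`tamvi` exposes each stage plus the clinician-facing calculator:

```bash
tamvi simulate --seed 7 --out cohort.csv --truth-out truth.csv
tamvi fit-irt --in cohort.csv --trial all --model both --out 'bank_t{trial}.json'
tamvi score --in cohort.csv --banks bank_t1.json ... --out theta.csv
tamvi fit-lmm --theta theta.csv --demographics cohort.csv --select sequential --out lmm.json
tamvi calculate --bundle bundle.json \
    --responses '{"6": [0,1,1,1,1,1,1,1,1,1,1,1]}' \
    --age 17 --sex girl --country Spain --mpe 18
```

`calculate` reads a single bundle JSON (six item banks + mixed model) and
prints θ, the adjusted z and the percentile per supplied trial.

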