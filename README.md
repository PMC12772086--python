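# canine-bst — behavioural susceptibility analysis of canine obesity

`bst` is a Python toolkit for testing the *behavioural susceptibility*
hypothesis in dogs: genetically driven variation in appetite (food
motivation) determines how strongly an obesogenic environment — ready food
access, lax owner management, little exercise — translates into adiposity.
It is written for veterinary epidemiologists and quantitative biologists
working with two kinds of data:

* **owner questionnaires** — Likert responses about a dog's eating
  behaviour (13 items) and the owner's management of diet and exercise
  (13 items), plus an owner-reported 9-point body condition score (BCS);
* **clinic records** — visit-level tables with breed, sex, whole-year age
  and a 5-point BCS.

## What it computes

**Questionnaire scoring.** Items are scored on [0, 1] (4-option scale:
1 / 0.6667 / 0.3333 / 0; 5-option scale: 1 / 0.75 / 0.5 / 0.25 / 0, with
reverse-keyed items flipped), grouped into six factors (each the sum of its
item scores over the summed maxima), and combined into the weighted
composites

    FMS = (7·RS + 3·LF + 3·IF) / 13        (food motivation)
    OCS = (4·OI + 4·RHF + 5·EX) / 13       (owner control)

**Breed obesity probabilities.** The 5-point clinic BCS is collapsed to
three categories (1–2 underweight, 3 ideal, 4–5 overweight/obese) and one
random visit is kept per dog. Because sparse breed × age × sex cells cause
separation, each category is modelled against the shared 'ideal' reference
with **Firth bias-reduced logistic regression**, maximising

    l*(β) = l(β) + ½ log det I(β),   I(β) = XᵀWX,  W = diag(πᵢ(1−πᵢ)),

whose modified score Uⱼ*(β) = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢⱼ is solved by
Newton iteration with step-halving; estimates stay finite even under
complete separation. The two binomial fits (terms Breed + YearOfAge + Sex
with Breed:Sex and Breed:YearOfAge interactions) are merged into a
three-category multinomial,

    p_ideal = 1 / (1 + e^{η_U} + e^{η_O}),  p_under = e^{η_U} p_ideal,
    p_over = e^{η_O} p_ideal,

and per-breed probabilities are **standardized** to the population age
distribution and a 50:50 sex ratio, with 95% confidence intervals obtained
by simulating coefficient vectors from each fit's asymptotic normal
distribution.

**Association analyses.** Breed-average food motivation (adjusted for
sex/neuter composition via the minimal stepwise-AIC model) is correlated
with standardized breed overweight/obesity probability; individual-level
correlations, R²/AIC model comparisons, and a tertile-stratified
interaction model quantify how owner management interacts with food
motivation.

**Synthetic cohorts.** `bst.synthetic` generates linked questionnaire and
clinic cohorts with known ground truth (breed latent food motivation,
breed obesity propensity correlated with it at an exact target), so every
stage is testable without access to the original data.

## Worked example

```python
from bst import PipelineConfig, SimConfig, run_full_analysis

config = PipelineConfig(sim=SimConfig(seed=1), n_draws=500)
report = run_full_analysis(config)

s = report.scored_summary
print(f"scored dyads retained : {report.filter_report.n_retained}")
print(f"FMS mean (sd)         : {s['fms_mean']:.3f} ({s['fms_sd']:.3f})")
a = report.breed_association
print(f"breed-level Pearson r : {a['pearson_r']:.3f} (p = {a['pearson_p']:.2e})")
print(f"breed-level R^2       : {a['r_squared']:.3f}")
```

prints

```
scored dyads retained : 13004
FMS mean (sd)         : 0.623 (0.259)
breed-level Pearson r : 0.635 (p = 2.13e-06)
breed-level R^2       : 0.403
```

13,004 of 14,960 simulated dyads survive the inclusion rules (age strictly
between 1 and 19 years, owner BCS above 3); the retained population has a
food-motivation composite centred near 0.62. Joining the 46 breeds present
in both arms, breed-average food motivation correlates strongly with the
standardized overweight/obesity probability (r = 0.64): with the generator's
breed-level target correlation of 0.7, this run recovers most of the built-in
signal, the shortfall being finite-sample estimation noise in both arms.
`report.breed_probability_table` holds the per-breed probability triples
with their simulation CIs, e.g.

```
   breed  p_overweight_obese  ci_low_overweight_obese  ci_high_overweight_obese
breed_01            0.348729                 0.279559                  0.422785
breed_02            0.392936                 0.293891                  0.492230
breed_03            0.404008                 0.351285                  0.454276
```

The same pipeline runs from the shell:

```bash
bst simulate --seed 1 --questionnaire-out q.csv --ehr-out ehr.csv
bst score --input q.csv --output scored.csv
bst filter --input scored.csv --output kept.csv --report filter.json
bst breed-probs --input ehr.csv --output breed_probs.csv
```

or end to end with `bst run-all --config config.yaml`, which writes all
result tables plus a `manifest.json` (seeds, config hash, versions)
sufficient to re-run the analysis bit-identically.

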