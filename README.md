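# gamblefit

Prospect-theory modelling of risky choice in two-option gamble tasks, built
for within-subject crossover studies (each subject tested under two
intervention conditions). It provides the full analysis chain used in
behavioural and computational-psychiatry work on risk preference:

- **Choice models.** Four nested value models for a gamble X = (r, p)
  (win magnitude r with probability p, else nothing):

  | model | V(X) | free parameters |
  |-------|------|-----------------|
  | 1 | r·p | β |
  | 2 | r^λ·p | λ, β |
  | 3 | r·w(p) | γ, β |
  | 4 | r^λ·w(p) | λ, γ, β |

  with the one-parameter Prelec weighting function
  w(p) = exp(−(−ln p)^γ) and a softmax choice rule on the value
  difference, P(A) = 1 / (1 + exp(−β(V_A − V_B))). λ is utility
  sensitivity (λ < 1 risk-averse), γ the probability-weighting exponent
  (γ < 1 inverse-S), β the inverse temperature.

- **Fitting.** Per-subject maximum likelihood (bounded multi-start, AIC),
  and hierarchical empirical Bayes by importance-sampling EM: gamma
  population priors, likelihood-weighted prior updates, per-subject
  posterior-weighted-mean estimates, and model comparison by the
  integrated BIC, iBIC = −2·Σ log evidence + (hyperparameters)·ln(total
  choices).

- **Group statistics.** Normality-gated paired contrasts (Shapiro–Wilk →
  paired t or Wilcoxon signed-rank with exact small-sample p), Cohen's dz,
  rationality contrasts on |λ−1| and |γ−1|, and noncentral-t power
  analysis.

- **Synthetic study generator.** A fully specified stand-in for the study
  design (33 subjects × 2 conditions × 120 trials, EV-matched safe/risky
  gamble pairs in JPY, correlated condition-specific gamma populations)
  with a recorded ground truth, so every estimator is validated by
  parameter and model recovery.

## Worked example

Simulate a full-size study from model 4, compare all four models by iBIC in
the neutral condition, then contrast the fitted λ between conditions:

```python
import numpy as np
import gamblefit as gf

study = gf.simulate_crossover_study(gf.StudyDesign(), gf.PopulationSpec(),
                                    model=4, seed=1)
comp = gf.compare_models_hbem(study.cohort("neutral"), (1, 2, 3, 4),
                              n_samples=20_000, seed=1)
print(comp.table.to_string(index=False))

fit_neu = comp.fits[4]
fit_pos = gf.fit_hbem(study.cohort("positive"), 4, n_samples=20_000, seed=1)
lam_neu = np.array([e.lam for e in fit_neu.per_subject_estimates])
lam_pos = np.array([e.lam for e in fit_pos.per_subject_estimates])
res = gf.paired_compare(lam_pos, lam_neu, variable="lam")
print(f"lam contrast: test={res.test_used} stat={res.statistic:.3f} "
      f"p={res.p_value:.2e} dz={res.effect_size_d:.3f}")
print("required n:", gf.required_sample_size(d=0.5, power=0.8, alpha=0.05))
```

Output:

```
 model_id  n_free_params  total_log_evidence        ibic  winner
        1              1        -2575.032087 5166.632173   False
        2              2        -2163.742561 4360.621120   False
        3              2        -2290.721082 4614.578161   False
        4              3        -1963.925895 3977.555785    True
lam contrast: test=wilcoxon stat=4.199 p=2.68e-05 dz=0.897
required n: 34
```

Model 4 (both nonlinearities) has the smallest iBIC, so its per-subject
estimates feed the contrast; the λ difference between conditions is
positive and significant, matching the effect the generator builds in
(larger λ in the positive condition). The power analysis says 34 pairs are
needed to detect dz = 0.5 at 80% power, two-sided α = 0.05.

The same workflow is available end to end as a pipeline
(`gf.run_study_pipeline(gf.RunConfig(...))`) or from the shell:

```sh
gamblefit run-all --seed 1 --n-samples 20000 --output-dir run1
```

which writes `model_comparison.csv`, `subject_parameters.csv`,
`contrasts.csv`, `priors.csv`, `recovery.csv` and a seed-stamped
`manifest.json`; identical config and seed reproduce every file byte for
byte.

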