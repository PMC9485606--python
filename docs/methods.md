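# Methods

## Choice models

A gamble X = (r, p) pays magnitude r (JPY) with probability p, else
nothing. Subjective value combines a power utility u(r) = r^λ with a
one-parameter Prelec decision weight w(p) = exp(−(−ln p)^γ); the four
candidate models free neither, one, or both nonlinearities (λ and γ fixed
at 1 when not free, so one likelihood implementation serves all four).
Choice between options A and B follows a logistic softmax on the value
difference, P(A) = 1/(1 + exp(−β(V_A − V_B))), β ≥ 0. The softmax is the
standard logistic-on-difference reading; a normalised-value variant was
not considered further.

Assumptions: reward-only gambles (no losses, so no loss-aversion term);
trials are conditionally independent given the parameters; sessions within
a condition are pooled; timed-out trials carry no information and are
excluded from the likelihood (the loader preserves them as `MISSING`).

Numerics: utilities are computed on r / 100 (units of 100 JPY,
`MAGNITUDE_SCALE`), keeping r^λ and hence β in a benign range compatible
with gamma priors; raw-JPY analysis is the `magnitude_scale=1` switch.
Per-trial choice probabilities are clipped to [1e−12, 1 − 1e−12] before
logs, so the likelihood stays finite at extreme β. All likelihood code is
log-space throughout (`log(P)` via `−logaddexp(0, −z)`), and the scalar
per-trial function and the vectorised engine agree to 1e−10.

## Maximum-likelihood fitting

Per subject and model, the negative log-likelihood is minimised by
L-BFGS-B in log-parameter space within bounds λ, γ ∈ [0.05, 3],
β ∈ [1e−4, 30] (scaled units; wide enough to cover plausible estimates
with margin while excluding flat degenerate regions). The surface is
multimodal in (λ, β), so 10 log-uniform random starts plus a deterministic
start at the unit point are used; the best optimum is returned with a
convergence flag, and the returned NLL is never above the objective at any
tried start. AIC = 2k + 2·NLL; cohort summaries report both the mean and
the sum of per-subject AIC, since either aggregation convention is in use.

## Hierarchical empirical Bayes (importance-sampling EM)

Population priors over each free parameter are gamma distributions,
initialised to shape 1, scale 3 (mean 3, variance 9 — at least 5% mass on
each of (0, 0.5], (0.5, 1.5], (1.5, 5]). One iteration:

1. draw n_samples parameter vectors from the current priors (the proposal
   is the prior itself; no adaptive proposals);
2. for each subject, importance weights ∝ exp(log-likelihood), and the
   log marginal evidence estimate logsumexp(loglik) − log n_samples;
3. M-step: moment-match new gamma priors to the cohort-pooled posterior
   mean μ and variance v (shape = μ²/v, scale = v/μ). Each subject
   contributes equally (average of per-subject posterior moments), so with
   unbalanced data no subject dominates; the pooled variance includes the
   between-subject spread of posterior means. Weighted ML gamma fitting
   would be an alternative M-step; moment matching is closed-form and
   stable.

Iteration stops when the total log evidence improves by less than 0.1 nats
("stopped increasing" made concrete) or at 50 iterations. Common random
numbers — one fixed uniform matrix pushed through the current priors'
inverse CDF every iteration — make the evidence trace comparable across
iterations; the trace and its Monte-Carlo standard error
(per subject, sqrt(Σw² − 1/n) in log space) are returned, and ascent holds
within 2 SE in tests. Per-subject estimates are posterior-weighted means
of the final sample set.

The default n_samples is 100,000; the validation suite and the acceptance
report use 5,000–20,000, which this package's recovery checks show is
sufficient at the default study size (the problem sizes used are stated in
the tests and in `scripts/acceptance.py`).

iBIC = −2·(total log evidence) + h·ln(total choices), with h counting the
group-level hyperparameters — 2 per gamma prior, so h = 2k for a k-free-
parameter model. Counting model parameters instead of hyperparameters is a
documented alternative convention; the hyperparameter count is used here.

## Synthetic study generator

The generator emulates the study design, not any particular dataset: the
original stimulus list is unpublished, so a principled stand-in is
produced. Each of 120 trials per condition pairs a safer option (higher p,
lower r) with a riskier one (lower p, higher r), expected values matched
within ±25%, probabilities drawn from
{0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0} and
magnitudes from 100–10,000 JPY. EV-matched pairs with both tail
probabilities present maximise information about λ and γ jointly; a level
set lacking a small (≤ 0.2) or large (≥ 0.8) probability is rejected as an
identifiability guard. All subjects and both conditions share one stimulus
list, as in a fixed-stimulus task.

Per-subject parameters are gamma-distributed per condition, coupled across
conditions by a Gaussian copula: z_cond = √ρ·z_shared + √(1−ρ)·ε, giving
latent correlation exactly ρ (default 0.6 — a crossover design implies
within-subject dependence, and independent draws would understate paired
power). Defaults: λ ~ Gamma(16, 0.05) neutral (mean 0.8, risk-averse) vs
Gamma(16, 0.059375) positive (mean 0.95, nearer risk-neutral);
γ ~ Gamma(16, 0.05625) neutral (mean 0.9) vs Gamma(16, 0.046875) positive
(mean 0.75, more strongly inverse-S); β ~ Gamma(4, 0.5) (mean 2, scaled
units) in both conditions. The directions (λ up, γ down in the positive
condition) are the package's emulated effect. With these defaults and
ρ = 0.6 the realised paired effect size on fitted λ is large (dz ≈ 0.6–0.9
across seeds) — comfortably detectable at n = 33; smaller shifts or lower
ρ weaken it in the obvious way. Timeouts are off by default
(`timeout_rate=0`), configurable.

Seeds are split (`numpy.random.SeedSequence.spawn`) into independent
streams for stimuli, population draws, choices, and condition order, so
each layer can be pinned separately; condition order is counterbalanced
(⌊n/2⌋ / ⌈n/2⌉ split, recorded but not analysed).

What the generator does **not** emulate: the real stimulus distribution
(and hence the true identifiability of the original study), response
times, session-order or fatigue effects, and any relation between the
interventions and mood/physiology. Passing recovery tests therefore shows
the estimators work at this design's scale and noise level, not that the
original dataset would yield the same parameter values.

## Group statistics

Within-subject contrasts (positive − neutral) are gated on normality of
the differences: Shapiro–Wilk p ≥ 0.05 selects the paired t-test,
otherwise the Wilcoxon signed-rank test. The gate threshold and
per-variable application are conventions fixed here (0.05, per variable).
Wilcoxon: zero differences dropped; exact two-sided p by the signed-rank
sign-flip distribution (dynamic-programming convolution, identical to
enumerating all 2^n sign vectors) for n ≤ 25 without ties; otherwise
midranks, tie-corrected variance, continuity correction, reported as a
signed Z. Effect size is Cohen's dz = mean(diff)/sd(diff) (matched-pairs
"difference" convention; other d conventions exist and would give
different values). Rationality contrasts apply the same machinery to
|λ − 1| and |γ − 1|, the distance from risk-neutrality / objective
weighting. The power routine finds the smallest n whose two-sided
one-sample t-test on differences, with noncentrality d√n, reaches the
target power (exact noncentral-t computation); d = 0.5, power 0.8,
α = 0.05 gives n = 34.

## Pipeline

`run_study_pipeline` chains simulation (or CSV loading), hierarchical and
ML fits of all candidate models per condition, iBIC/AIC comparison, the
winning model's subject tables, all paired contrasts under both methods,
final population-prior summaries per condition, and (in simulate mode) a
truth-recovery table. Every CSV embeds the SHA-256 manifest hash of the
config; identical config + seed reproduce outputs byte for byte. The
winning model is the smallest summed iBIC across conditions.

## Known limitations

- Prior-as-proposal importance sampling degrades when a subject's
  likelihood is much narrower than the prior (low effective sample size in
  early iterations); the evidence SE in the trace makes this visible, and
  degenerate subjects (all likelihoods at the floor) are flagged.
- Moment-matched EM is not a strict ascent algorithm on the marginal
  evidence; in practice the trace rises and plateaus within Monte-Carlo
  noise.
- ML standard errors / credible intervals are out of scope, as are loss
  gambles, two-parameter weighting functions, and response-time models.
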