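"""Hierarchical empirical-Bayes fitting by importance-sampling EM.

The population distribution of each free parameter is a gamma prior. One EM
iteration: draw ``n_samples`` parameter vectors from the current priors
(E-step proposal), weight each sample by every subject's choice likelihood
(importance weights), estimate each subject's log marginal evidence by the
Monte-Carlo average of the likelihood under the prior, then moment-match new
gamma priors to the cohort-pooled posterior mean and variance (M-step).
Iteration stops when the total log evidence improves by less than ``tol``
nats. Per-subject parameter estimates are posterior-weighted means of the
final sample set.

Common random numbers: by default the same uniform matrix is pushed through
the inverse gamma CDF of the current priors at every iteration, so the
evidence trace is comparable across iterations (fresh draws are an option).

Model comparison uses the integrated BIC

    iBIC = -2 * total_log_evidence + n_hyperparams * ln(total_choices),

where ``n_hyperparams`` counts the group-level gamma hyperparameters
(shape and scale per free parameter, i.e. 2 per prior); smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .models import (
    MAGNITUDE_SCALE,
    ModelSpec,
    ParameterSet,
    SubjectDataset,
    cohort_log_likelihoods,
    get_model,
)

#: Default initial gamma prior for every free parameter: shape 1, scale 3
#: (mean 3, variance 9, mode 0) — broad over the plausible (0, ~10] range.
INIT_SHAPE = 1.0
INIT_SCALE = 3.0


@dataclass(frozen=True)
class GammaPrior:
    """Group-level gamma prior; mean = shape*scale, var = shape*scale**2."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("gamma shape and scale must be > 0")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return sps.gamma.ppf(u, a=self.shape, scale=self.scale)


@dataclass(frozen=True)
class PriorSet:
    """One GammaPrior per free parameter of a model, in free-name order."""

    priors: dict[str, GammaPrior]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.priors)

    def __getitem__(self, name: str) -> GammaPrior:
        return self.priors[name]

    @property
    def n_hyperparams(self) -> int:
        return 2 * len(self.priors)


@dataclass
class HBEMFitResult:
    """Converged hierarchical fit of one model to one cohort."""

    model_id: int
    final_priors: PriorSet
    per_subject_estimates: list[ParameterSet]
    per_subject_log_evidence: np.ndarray
    total_log_evidence: float
    ibic: float
    evidence_trace: list[tuple[float, float]]  # (total log evidence, MC SE)
    n_samples: int
    seed: int
    n_iterations: int
    subject_ids: list[str] = field(default_factory=list)
    degenerate_subjects: list[str] = field(default_factory=list)


def init_priors(model: int | ModelSpec) -> PriorSet:
    """Broad initial priors (shape 1, scale 3) for every free parameter."""
    m = get_model(model)
    return PriorSet({name: GammaPrior(INIT_SHAPE, INIT_SCALE) for name in m.free_names})


def draw_parameter_samples(
    priors: PriorSet,
    n_samples: int,
    seed: int | None = None,
    uniforms: np.ndarray | None = None,
) -> np.ndarray:
    """(n_samples, k) independent gamma draws, one column per free parameter.

    If ``uniforms`` is given (same shape), samples are the inverse-CDF
    transform of those uniforms — the common-random-numbers path used by the
    EM loop; otherwise fresh draws from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    k = len(priors.names)
    if uniforms is None:
        rng = np.random.default_rng(seed)
        uniforms = rng.random((n_samples, k))
    if uniforms.shape != (n_samples, k):
        raise ValueError("uniforms must have shape (n_samples, n_free_params)")
    out = np.empty_like(uniforms)
    for j, name in enumerate(priors.names):
        out[:, j] = priors[name].ppf(uniforms[:, j])
    return out


def _full_columns(
    samples: np.ndarray, names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a (S, k) free-parameter matrix to full (lam, gam, beta) arrays."""
    s = samples.shape[0]
    ones = np.ones(s)
    cols = {name: samples[:, j] for j, name in enumerate(names)}
    return cols.get("lam", ones), cols.get("gam", ones), cols.get("beta", ones)


def _weights_from_loglik(loglik: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Normalised importance weights, log evidence, and its Monte-Carlo SE.

    log evidence = logsumexp(loglik) - log S; the SE of the log estimate is
    sqrt(sum w^2 - 1/S) (the coefficient of variation of the raw weights
    over sqrt(S)).
    """
    s = loglik.shape[0]
    log_z = float(logsumexp(loglik))
    w = np.exp(loglik - log_z)
    log_evidence = log_z - np.log(s)
    se = float(np.sqrt(max(np.sum(w**2) - 1.0 / s, 0.0)))
    return w, log_evidence, se


def subject_importance_weights(
    data: SubjectDataset,
    samples: np.ndarray,
    model: int | ModelSpec,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> tuple[np.ndarray, float]:
    """Normalised likelihood weights and log marginal evidence for a subject.

    Weight_i is proportional to exp(loglik_i); everything is computed in log
    space, so only likelihood *differences* matter and a uniform NLL offset
    cancels.
    """
    m = get_model(model)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError("samples must be a nonempty (S, k) matrix")
    lam, gam, beta = _full_columns(samples, m.free_names)
    loglik = cohort_log_likelihoods([data], lam, gam, beta, m, magnitude_scale)[0]
    w, log_evidence, _ = _weights_from_loglik(loglik)
    return w, log_evidence


def update_priors(
    samples: np.ndarray,
    per_subject_weights: np.ndarray,
    names: tuple[str, ...],
) -> PriorSet:
    """Moment-match new gamma priors to the cohort-pooled posterior moments.

    Each subject contributes equally: the pooled mean and second moment are
    simple averages of per-subject posterior moments (so the pooled variance
    includes the between-subject spread of posterior means). shape = mu^2/v,
    scale = v/mu.
    """
    w = np.atleast_2d(per_subject_weights)
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("per-subject weights must each sum to 1")
    priors: dict[str, GammaPrior] = {}
    for j, name in enumerate(names):
        x = samples[:, j]
        m1 = w @ x  # per-subject posterior means
        m2 = w @ x**2  # per-subject posterior second moments
        mu = float(m1.mean())
        v = float(m2.mean() - mu**2)
        if v <= 0:
            raise ValueError(
                f"degenerate posterior variance for {name}; cannot moment-match"
            )
        priors[name] = GammaPrior(shape=mu**2 / v, scale=v / mu)
    return PriorSet(priors)


def fit_hbem(
    cohort: Sequence[SubjectDataset],
    model: int | ModelSpec,
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 0.1,
    max_iter: int = 50,
    common_random_numbers: bool = True,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> HBEMFitResult:
    """Importance-sampling EM fit of one model to a cohort.

    Alternates sampling from the current priors, importance weighting by
    each subject's likelihood, and moment-matched prior updates, stopping
    when the total log evidence improves by less than ``tol`` nats (default
    0.1) or after ``max_iter`` iterations. Per-subject estimates are the
    posterior-weighted means of the final sample set.
    """
    m = get_model(model)
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    names = m.free_names
    k = len(names)
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_samples, k)) if common_random_numbers else None

    priors = init_priors(m)
    trace: list[tuple[float, float]] = []
    prev_total = -np.inf
    samples = None
    weights = np.empty((len(cohort), n_samples))
    log_ev = np.empty(len(cohort))
    n_iter = 0
    floor_ll = np.array([d.n_usable for d in cohort]) * np.log(1e-12)
    degenerate = np.zeros(len(cohort), bool)
    for n_iter in range(1, max_iter + 1):
        if common_random_numbers:
            samples = draw_parameter_samples(priors, n_samples, uniforms=uniforms)
        else:
            samples = draw_parameter_samples(
                priors, n_samples, seed=int(rng.integers(2**31 - 1))
            )
        lam, gam, beta = _full_columns(samples, names)
        loglik = cohort_log_likelihoods(cohort, lam, gam, beta, m, magnitude_scale)
        total_var = 0.0
        for i in range(len(cohort)):
            w, le, se = _weights_from_loglik(loglik[i])
            weights[i], log_ev[i] = w, le
            total_var += se**2
            degenerate[i] = bool(np.max(loglik[i]) <= floor_ll[i] * 0.999999)
        total = float(log_ev.sum())
        trace.append((total, float(np.sqrt(total_var))))
        if degenerate.all():
            raise ValueError("all subjects degenerate (likelihoods at the floor)")
        if total - prev_total < tol and n_iter > 1:
            break
        prev_total = total
        if n_iter < max_iter:
            priors = update_priors(samples, weights, names)

    estimates = []
    for i in range(len(cohort)):
        theta = dict(zip(names, weights[i] @ samples))
        estimates.append(
            ParameterSet(
                lam=float(theta.get("lam", 1.0)),
                gam=float(theta.get("gam", 1.0)),
                beta=float(theta.get("beta", 1.0)),
            )
        )
    total = float(log_ev.sum())
    total_choices = int(sum(d.n_usable for d in cohort))
    return HBEMFitResult(
        model_id=m.model_id,
        final_priors=priors,
        per_subject_estimates=estimates,
        per_subject_log_evidence=log_ev.copy(),
        total_log_evidence=total,
        ibic=ibic(total, 2 * k, total_choices),
        evidence_trace=trace,
        n_samples=n_samples,
        seed=seed,
        n_iterations=n_iter,
        subject_ids=[d.subject_id for d in cohort],
        degenerate_subjects=[
            d.subject_id for d, flag in zip(cohort, degenerate) if flag
        ],
    )


def ibic(total_log_evidence: float, n_hyperparams: int, total_choices: int) -> float:
    """Integrated BIC: -2 * total evidence + n_hyperparams * ln(total choices)."""
    if total_choices < 1:
        raise ValueError("total_choices must be >= 1")
    return -2.0 * total_log_evidence + n_hyperparams * np.log(total_choices)


@dataclass
class ModelComparison:
    """iBIC table over candidate models with the winner marked."""

    table: pd.DataFrame
    winner: int
    fits: dict[int, HBEMFitResult]


def compare_models_hbem(
    cohort: Sequence[SubjectDataset],
    models: Sequence[int | ModelSpec] = (1, 2, 3, 4),
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 0.1,
    max_iter: int = 50,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> ModelComparison:
    """Fit each candidate model with common seeds and rank by iBIC."""
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    fits: dict[int, HBEMFitResult] = {}
    rows = []
    for model in models:
        m = get_model(model)
        fit = fit_hbem(
            cohort,
            m,
            n_samples=n_samples,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
            magnitude_scale=magnitude_scale,
        )
        fits[m.model_id] = fit
        rows.append(
            {
                "model_id": m.model_id,
                "n_free_params": m.n_free_params,
                "total_log_evidence": fit.total_log_evidence,
                "ibic": fit.ibic,
                "n_iterations": fit.n_iterations,
            }
        )
    table = pd.DataFrame(rows)
    winner = int(table.loc[table["ibic"].idxmin(), "model_id"])
    table["winner"] = table["model_id"] == winner
    return ModelComparison(table=table, winner=winner, fits=fits)
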