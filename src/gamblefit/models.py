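"""Prospect-theory value models and the softmax choice likelihood.

Four nested models of risky choice between two described gambles, each a
(magnitude r, probability p) pair:

    model 1:  V(X) = r p                      (expected value; beta only)
    model 2:  V(X) = r**lam * p               (power utility)
    model 3:  V(X) = r * w(p)                 (Prelec probability weighting)
    model 4:  V(X) = r**lam * w(p)            (both nonlinearities)

with the one-parameter Prelec weighting function

    w(p) = exp(-(-ln p)**gam),

and a logistic (softmax) choice rule on the value difference,

    P(choose A) = 1 / (1 + exp(-beta * (V_A - V_B))).

``lam`` is utility sensitivity (lam < 1 concave/risk-averse), ``gam`` the
probability-weighting exponent (gam < 1 inverse-S), ``beta`` the inverse
temperature. Parameters a model does not free are fixed at 1, so one
likelihood implementation serves all four models.

Magnitudes reach the likelihood in JPY; utilities are computed on
magnitude / ``MAGNITUDE_SCALE`` (units of 100 JPY) so that r**lam and hence
beta stay in a numerically benign range. ``power_utility``/``option_value``
themselves are pure in whatever units the caller passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# -- module-wide numerical configuration -------------------------------------

#: JPY per utility unit: likelihoods evaluate utilities on magnitude/100,
#: recovering the dollar scale of the original stimulus set (which was
#: converted to JPY by multiplying by 100). Pass ``magnitude_scale=1.0`` to
#: likelihood functions to work on raw magnitudes instead.
MAGNITUDE_SCALE = 100.0

#: Per-trial choice probabilities are clipped to [PROB_FLOOR, 1 - PROB_FLOOR]
#: before taking logs, so the likelihood stays finite at extreme beta.
PROB_FLOOR = 1e-12
_LOG_FLOOR = math.log(PROB_FLOOR)
_LOG_CEIL = math.log1p(-PROB_FLOOR)

CHOICE_A = "A"
CHOICE_B = "B"
MISSING = "MISSING"

CONDITIONS = ("neutral", "positive")


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class GambleOption:
    """One gamble: win ``magnitude`` (JPY) with ``probability``, else nothing."""

    magnitude: float
    probability: float

    def __post_init__(self) -> None:
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")
        if not 0 < self.probability <= 1:
            raise ValueError(
                f"probability must be in (0, 1], got {self.probability}"
            )


@dataclass(frozen=True)
class GambleTrial:
    """One two-option choice trial.

    ``choice`` is "A", "B", "MISSING" (timeout), or None for a stimulus frame
    whose choice has not been made/simulated yet.
    """

    option_a: GambleOption
    option_b: GambleOption
    choice: str | None = None
    session: int = 1

    def __post_init__(self) -> None:
        if self.choice not in (CHOICE_A, CHOICE_B, MISSING, None):
            raise ValueError(f"invalid choice {self.choice!r}")
        if (
            self.option_a.magnitude == self.option_b.magnitude
            and self.option_a.probability == self.option_b.probability
        ):
            raise ValueError("options must not be identical")


@dataclass
class SubjectDataset:
    """All trials of one subject under one condition (sessions pooled)."""

    subject_id: str
    condition: str
    trials: list[GambleTrial]
    _arrays: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_usable == 0:
            raise ValueError("dataset needs at least one non-missing trial")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_usable(self) -> int:
        return sum(1 for t in self.trials if t.choice in (CHOICE_A, CHOICE_B))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(r_a, p_a, r_b, p_b, chose_a) over non-missing trials, cached."""
        if self._arrays is None:
            usable = [t for t in self.trials if t.choice in (CHOICE_A, CHOICE_B)]
            self._arrays = (
                np.array([t.option_a.magnitude for t in usable]),
                np.array([t.option_a.probability for t in usable]),
                np.array([t.option_b.magnitude for t in usable]),
                np.array([t.option_b.probability for t in usable]),
                np.array([1.0 if t.choice == CHOICE_A else 0.0 for t in usable]),
            )
        return self._arrays


@dataclass(frozen=True)
class ModelSpec:
    """Which value-function components a model frees (plus beta, always free)."""

    model_id: int
    uses_nonlinear_utility: bool
    uses_nonlinear_weighting: bool

    @property
    def n_free_params(self) -> int:
        return 1 + self.uses_nonlinear_utility + self.uses_nonlinear_weighting

    @property
    def free_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.uses_nonlinear_utility:
            names.append("lam")
        if self.uses_nonlinear_weighting:
            names.append("gam")
        names.append("beta")
        return tuple(names)


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, False, False),
    2: ModelSpec(2, True, False),
    3: ModelSpec(3, False, True),
    4: ModelSpec(4, True, True),
}


def get_model(model: int | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model id {model!r}; valid ids are 1-4") from None


@dataclass(frozen=True)
class ParameterSet:
    """(lam, gam, beta) for one subject; fixed components are stored as 1."""

    lam: float = 1.0
    gam: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if not self.gam > 0:
            raise ValueError(f"gam must be > 0, got {self.gam}")
        if not self.beta >= 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def effective(self, model: int | ModelSpec) -> "ParameterSet":
        """Parameters with components the model does not free pinned at 1."""
        m = get_model(model)
        return ParameterSet(
            lam=self.lam if m.uses_nonlinear_utility else 1.0,
            gam=self.gam if m.uses_nonlinear_weighting else 1.0,
            beta=self.beta,
        )


# -- elementary value functions -----------------------------------------------


def power_utility(r, lam):
    """Power utility u(r) = r**lam. Accepts scalars or arrays; r, lam > 0."""
    r = np.asarray(r, dtype=float)
    lam_a = np.asarray(lam, dtype=float)
    if np.any(r <= 0):
        raise ValueError("magnitude r must be > 0")
    if np.any(lam_a <= 0):
        raise ValueError("utility exponent lam must be > 0")
    out = r ** lam_a
    return float(out) if out.ndim == 0 else out


def prelec_weight(p, gam):
    """One-parameter Prelec weight w(p) = exp(-(-ln p)**gam) on (0, 1].

    gam = 1 is the identity; gam < 1 the inverse-S shape (overweighting
    small, underweighting large probabilities); the fixed point is p = 1/e
    for every gam.
    """
    p = np.asarray(p, dtype=float)
    gam_a = np.asarray(gam, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("probability p must be in (0, 1]")
    if np.any(gam_a <= 0):
        raise ValueError("weighting exponent gam must be > 0")
    out = np.exp(-((-np.log(p)) ** gam_a))
    return float(out) if out.ndim == 0 else out


def option_value(
    option: GambleOption,
    params: ParameterSet,
    model: int | ModelSpec,
) -> float:
    """Subjective value of a gamble under one of the four models.

    Pure in the caller's magnitude units; the likelihood layer applies the
    JPY scaling before calling into the same arithmetic.
    """
    m = get_model(model)
    r, p = option.magnitude, option.probability
    u = power_utility(r, params.lam) if m.uses_nonlinear_utility else r
    w = prelec_weight(p, params.gam) if m.uses_nonlinear_weighting else p
    return float(u * w)


def choice_probability(v_a, v_b, beta) -> float:
    """Softmax probability of choosing A: 1 / (1 + exp(-beta (v_a - v_b))).

    Numerically stable for arbitrarily large |beta * (v_a - v_b)|.
    """
    beta_a = np.asarray(beta, dtype=float)
    if np.any(beta_a < 0):
        raise ValueError(f"inverse temperature beta must be >= 0, got {beta}")
    z = beta_a * (np.asarray(v_a, float) - np.asarray(v_b, float))
    out = np.exp(-np.logaddexp(0.0, -z))
    return float(out) if out.ndim == 0 else out


# -- vectorised likelihood engine ---------------------------------------------


def _log_choice_prob_matrices(
    r_a: np.ndarray,
    p_a: np.ndarray,
    r_b: np.ndarray,
    p_b: np.ndarray,
    lam: np.ndarray,
    gam: np.ndarray,
    beta: np.ndarray,
    model: ModelSpec,
    magnitude_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(S, T) matrices of floored log P(A) and log P(B).

    S parameter rows x T trials; fixed components of the model are ignored
    (treated as 1) regardless of the values passed.
    """
    rs_a = r_a[None, :] / magnitude_scale
    rs_b = r_b[None, :] / magnitude_scale
    if model.uses_nonlinear_utility:
        u_a = rs_a ** lam[:, None]
        u_b = rs_b ** lam[:, None]
    else:
        u_a, u_b = rs_a, rs_b
    if model.uses_nonlinear_weighting:
        w_a = np.exp(-((-np.log(p_a[None, :])) ** gam[:, None]))
        w_b = np.exp(-((-np.log(p_b[None, :])) ** gam[:, None]))
    else:
        w_a, w_b = p_a[None, :], p_b[None, :]
    z = beta[:, None] * (u_a * w_a - u_b * w_b)
    log_pa = -np.logaddexp(0.0, -z)
    log_pb = -np.logaddexp(0.0, z)
    np.clip(log_pa, _LOG_FLOOR, _LOG_CEIL, out=log_pa)
    np.clip(log_pb, _LOG_FLOOR, _LOG_CEIL, out=log_pb)
    return log_pa, log_pb


def _subject_log_likelihoods(
    data: SubjectDataset,
    lam: np.ndarray,
    gam: np.ndarray,
    beta: np.ndarray,
    model: ModelSpec,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> np.ndarray:
    """Length-S vector of summed per-trial log-likelihoods for one subject."""
    r_a, p_a, r_b, p_b, chose_a = data.arrays()
    log_pa, log_pb = _log_choice_prob_matrices(
        r_a, p_a, r_b, p_b, lam, gam, beta, model, magnitude_scale
    )
    return log_pa @ chose_a + log_pb @ (1.0 - chose_a)


def cohort_log_likelihoods(
    cohort: Sequence[SubjectDataset],
    lam: np.ndarray,
    gam: np.ndarray,
    beta: np.ndarray,
    model: int | ModelSpec,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> np.ndarray:
    """(n_subjects, S) log-likelihood matrix for S parameter vectors.

    Subjects sharing an identical stimulus list (the usual case: one fixed
    stimulus set for the whole study) share a single evaluation of the
    softmax log-probability matrices, which dominates the cost.
    """
    m = get_model(model)
    lam = np.atleast_1d(np.asarray(lam, float))
    gam = np.atleast_1d(np.asarray(gam, float))
    beta = np.atleast_1d(np.asarray(beta, float))
    out = np.empty((len(cohort), lam.shape[0]))
    groups: dict[bytes, list[int]] = {}
    for i, data in enumerate(cohort):
        r_a, p_a, r_b, p_b, _ = data.arrays()
        key = b"".join(a.tobytes() for a in (r_a, p_a, r_b, p_b))
        groups.setdefault(key, []).append(i)
    for idxs in groups.values():
        r_a, p_a, r_b, p_b, _ = cohort[idxs[0]].arrays()
        log_pa, log_pb = _log_choice_prob_matrices(
            r_a, p_a, r_b, p_b, lam, gam, beta, m, magnitude_scale
        )
        for i in idxs:
            chose_a = cohort[i].arrays()[4]
            out[i] = log_pa @ chose_a + log_pb @ (1.0 - chose_a)
    return out


# -- scalar likelihood API ----------------------------------------------------


def trial_log_likelihood(
    trial: GambleTrial,
    params: ParameterSet,
    model: int | ModelSpec,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> float:
    """Floored log-probability of the observed choice on one trial."""
    if trial.choice not in (CHOICE_A, CHOICE_B):
        raise ValueError(
            "trial has no usable choice; filter MISSING trials before scoring"
        )
    m = get_model(model)
    pe = params.effective(m)
    scaled = ParameterSet(pe.lam, pe.gam, pe.beta)
    v_a = option_value(
        GambleOption(trial.option_a.magnitude / magnitude_scale, trial.option_a.probability),
        scaled,
        m,
    )
    v_b = option_value(
        GambleOption(trial.option_b.magnitude / magnitude_scale, trial.option_b.probability),
        scaled,
        m,
    )
    z = pe.beta * (v_a - v_b)
    if trial.choice == CHOICE_B:
        z = -z
    log_p_chosen = -np.logaddexp(0.0, -z)
    return float(np.clip(log_p_chosen, _LOG_FLOOR, _LOG_CEIL))


def dataset_negative_log_likelihood(
    data: SubjectDataset,
    params: ParameterSet,
    model: int | ModelSpec,
    magnitude_scale: float = MAGNITUDE_SCALE,
) -> float:
    """Summed negative log-likelihood over the non-missing trials."""
    m = get_model(model)
    if data.n_usable == 0:
        raise ValueError("no usable trials")
    pe = params.effective(m)
    ll = _subject_log_likelihoods(
        data,
        np.array([pe.lam]),
        np.array([pe.gam]),
        np.array([pe.beta]),
        m,
        magnitude_scale,
    )
    return float(-ll[0])
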