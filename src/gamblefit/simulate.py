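"""Synthetic two-condition crossover study of risky choice.

Generates what the study design implies: a fixed list of two-option gamble
stimuli shared by all subjects, per-subject prospect-theory parameters drawn
from condition-specific gamma populations (correlated within subject across
conditions through a Gaussian copula), and softmax choices simulated from one
of the four value models. The generating parameters are kept as a truth
record so estimators can be validated by parameter recovery.

Stimulus stand-in: the original task reused a published stimulus list that
is not itself published, so the generator produces a principled replacement:
each trial pairs a safer option (higher probability, lower magnitude) with a
riskier one (lower probability, higher magnitude), matched in expected value
within a configurable ratio, over probability levels spanning both small
(<= 0.2) and large (>= 0.8) values so that utility curvature and probability
weighting are separately identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .models import (
    CHOICE_A,
    CHOICE_B,
    CONDITIONS,
    MAGNITUDE_SCALE,
    MISSING,
    GambleOption,
    GambleTrial,
    ModelSpec,
    ParameterSet,
    SubjectDataset,
    _log_choice_prob_matrices,
    get_model,
)

PARAM_NAMES = ("lam", "gam", "beta")

#: Probability levels of the stimulus stand-in; cover both tails so that
#: gamma (probability weighting) and lambda (utility curvature) are
#: separately identifiable.
DEFAULT_PROBABILITY_LEVELS = (
    0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale of one gamma marginal; mean = shape*scale."""

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


@dataclass(frozen=True)
class PopulationSpec:
    """Condition-specific gamma populations for (lam, gam, beta).

    ``rho`` is the within-subject correlation of the latent standard-normal
    deviates shared across conditions (Gaussian copula): the same subject's
    neutral and positive parameters are positively dependent, as a crossover
    design implies. rho = 0 gives independent draws, rho = 1 (with equal
    hyperparameters) identical ones.

    The defaults emulate the study's reported direction of effects: the
    positive condition has larger lam (mean 0.95 vs 0.8) and smaller gam
    (mean 0.75 vs 0.9) than neutral, beta identical (mean 2 on scaled
    magnitudes).
    """

    lam: dict[str, GammaParams] = field(
        default_factory=lambda: {
            "neutral": GammaParams(16.0, 0.05),
            "positive": GammaParams(16.0, 0.059375),
        }
    )
    gam: dict[str, GammaParams] = field(
        default_factory=lambda: {
            "neutral": GammaParams(16.0, 0.05625),
            "positive": GammaParams(16.0, 0.046875),
        }
    )
    beta: dict[str, GammaParams] = field(
        default_factory=lambda: {
            "neutral": GammaParams(4.0, 0.5),
            "positive": GammaParams(4.0, 0.5),
        }
    )
    rho: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        for name in PARAM_NAMES:
            marginals = getattr(self, name)
            if set(marginals) != set(CONDITIONS):
                raise ValueError(
                    f"{name} must define marginals for conditions {CONDITIONS}"
                )

    def marginal(self, name: str, condition: str) -> GammaParams:
        return getattr(self, name)[condition]


@dataclass(frozen=True)
class StudyDesign:
    """Size and stimulus layout of the simulated study.

    Defaults mirror the emulated study: 33 analysed subjects, 120 trials per
    condition split over 2 sessions, magnitudes 100-10,000 JPY, expected
    values of paired options matched within +/-25%.
    """

    n_subjects: int = 33
    trials_per_condition: int = 120
    sessions_per_condition: int = 2
    probability_levels: tuple[float, ...] = DEFAULT_PROBABILITY_LEVELS
    magnitude_range: tuple[float, float] = (100.0, 10_000.0)
    ev_tolerance: float = 0.25
    timeout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.trials_per_condition <= 0:
            raise ValueError("counts must be > 0")
        if not all(0 < p <= 1 for p in self.probability_levels):
            raise ValueError("probability levels must lie in (0, 1]")
        lo, hi = self.magnitude_range
        if not 0 < lo < hi:
            raise ValueError("magnitude_range must satisfy 0 < low < high")
        if not 0 <= self.timeout_rate < 1:
            raise ValueError("timeout_rate must be in [0, 1)")


def generate_gamble_set(design: StudyDesign, seed: int) -> list[GambleTrial]:
    """Stimulus frames (choices unset) for one condition's worth of trials.

    Each frame pairs a safer option (higher p, lower r) with a riskier one
    (lower p, higher r); which of the two is presented as option A is
    randomised. Raises if the probability levels do not include both a small
    (<= 0.2) and a large (>= 0.8) level, without which the weighting and
    utility exponents are poorly identifiable.
    """
    levels = np.array(sorted(design.probability_levels))
    if not (levels.min() <= 0.2 and levels.max() >= 0.8):
        raise ValueError(
            "probability levels must include a small (<= 0.2) and a large "
            "(>= 0.8) value for lam/gam identifiability"
        )
    rng = np.random.default_rng(seed)
    lo, hi = design.magnitude_range
    trials: list[GambleTrial] = []
    n = design.trials_per_condition
    per_session = int(np.ceil(n / design.sessions_per_condition))
    for i in range(n):
        while True:
            p_risky, p_safe = np.sort(rng.choice(levels, size=2, replace=False))
            r_risky = float(rng.uniform(lo, hi))
            ev_ratio = float(
                rng.uniform(1 - design.ev_tolerance, 1 + design.ev_tolerance)
            )
            r_safe = r_risky * (p_risky / p_safe) * ev_ratio
            if lo <= r_safe < r_risky:
                break
        safe = GambleOption(round(r_safe, 0), float(p_safe))
        risky = GambleOption(round(r_risky, 0), float(p_risky))
        a, b = (safe, risky) if rng.random() < 0.5 else (risky, safe)
        trials.append(
            GambleTrial(a, b, choice=None, session=1 + i // per_session)
        )
    return trials


def sample_population_parameters(
    pop: PopulationSpec,
    n_subjects: int,
    seed: int,
) -> list[dict[str, ParameterSet]]:
    """Per-subject (neutral, positive) ParameterSets with gamma marginals.

    A shared standard-normal deviate per subject and parameter induces
    correlation rho across conditions; the gamma marginal of each condition
    is recovered by the inverse-CDF (Gaussian copula) transform.
    """
    rng = np.random.default_rng(seed)
    rho = pop.rho
    values: dict[str, dict[str, np.ndarray]] = {}
    for name in PARAM_NAMES:
        z_shared = rng.standard_normal(n_subjects)
        values[name] = {}
        for condition in CONDITIONS:
            eps = rng.standard_normal(n_subjects)
            # corr(z_neutral, z_positive) = rho via the shared deviate
            z = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * eps
            u = sps.norm.cdf(z)
            g = pop.marginal(name, condition)
            values[name][condition] = sps.gamma.ppf(u, a=g.shape, scale=g.scale)
    out = []
    for i in range(n_subjects):
        out.append(
            {
                condition: ParameterSet(
                    lam=float(values["lam"][condition][i]),
                    gam=float(values["gam"][condition][i]),
                    beta=float(values["beta"][condition][i]),
                )
                for condition in CONDITIONS
            }
        )
    return out


def simulate_subject_choices(
    stimuli: Sequence[GambleTrial],
    params: ParameterSet,
    model: int | ModelSpec,
    seed: int,
    subject_id: str = "sim",
    condition: str = "neutral",
    timeout_rate: float = 0.0,
) -> SubjectDataset:
    """Sample one choice per stimulus frame from the softmax rule."""
    if len(stimuli) == 0:
        raise ValueError("stimuli must be nonempty")
    m = get_model(model)
    pe = params.effective(m)
    rng = np.random.default_rng(seed)
    r_a = np.array([t.option_a.magnitude for t in stimuli])
    p_a = np.array([t.option_a.probability for t in stimuli])
    r_b = np.array([t.option_b.magnitude for t in stimuli])
    p_b = np.array([t.option_b.probability for t in stimuli])
    log_pa, _ = _log_choice_prob_matrices(
        r_a,
        p_a,
        r_b,
        p_b,
        np.array([pe.lam]),
        np.array([pe.gam]),
        np.array([pe.beta]),
        m,
        magnitude_scale=MAGNITUDE_SCALE,
    )
    p_choose_a = np.exp(log_pa[0])
    chose_a = rng.random(len(stimuli)) < p_choose_a
    timeouts = (
        rng.random(len(stimuli)) < timeout_rate
        if timeout_rate > 0
        else np.zeros(len(stimuli), bool)
    )
    trials = [
        GambleTrial(
            t.option_a,
            t.option_b,
            MISSING if to else (CHOICE_A if a else CHOICE_B),
            t.session,
        )
        for t, a, to in zip(stimuli, chose_a, timeouts)
    ]
    return SubjectDataset(subject_id, condition, trials)


@dataclass
class CrossoverStudy:
    """Simulated cohort plus the generating truth record."""

    design: StudyDesign
    model_id: int
    stimuli: list[GambleTrial]
    datasets: dict[str, list[SubjectDataset]]  # condition -> per-subject data
    true_params: list[dict[str, ParameterSet]]  # per subject, per condition
    condition_order: list[str]  # "positive-first" / "neutral-first"
    seed: int

    def cohort(self, condition: str) -> list[SubjectDataset]:
        return self.datasets[condition]

    @property
    def all_datasets(self) -> list[SubjectDataset]:
        return [d for condition in CONDITIONS for d in self.datasets[condition]]

    def true_values(self, name: str, condition: str) -> np.ndarray:
        return np.array(
            [getattr(p[condition], name) for p in self.true_params]
        )

    def truth_to_json(self, path) -> None:
        rec = {
            "model_id": self.model_id,
            "seed": self.seed,
            "subjects": [
                {
                    "subject_id": self.datasets["neutral"][i].subject_id,
                    "condition_order": self.condition_order[i],
                    **{
                        condition: asdict(self.true_params[i][condition])
                        for condition in CONDITIONS
                    },
                }
                for i in range(self.design.n_subjects)
            ],
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1)

    @staticmethod
    def truth_from_json(path) -> dict:
        with open(path) as fh:
            rec = json.load(fh)
        for sub in rec["subjects"]:
            for condition in CONDITIONS:
                sub[condition] = ParameterSet(**sub[condition])
        return rec


def simulate_crossover_study(
    design: StudyDesign,
    pop: PopulationSpec,
    model: int | ModelSpec,
    seed: int | None = None,
) -> CrossoverStudy:
    """Simulate the full two-condition crossover study.

    Seeds are split into independent streams for stimuli, population
    parameters, choices, and condition order, so each layer can be pinned
    separately. All subjects and both conditions share one stimulus list, as
    in a fixed-stimulus task; condition order is counterbalanced (floor/ceil
    of n/2 subjects receive the positive condition first).
    """
    m = get_model(model)
    base = design.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    stim_seed, param_seed, choice_seed, order_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    stimuli = generate_gamble_set(design, stim_seed)
    truth = sample_population_parameters(pop, design.n_subjects, param_seed)
    order_rng = np.random.default_rng(order_seed)
    n = design.n_subjects
    orders = ["positive-first"] * (n // 2) + ["neutral-first"] * (n - n // 2)
    order_rng.shuffle(orders)
    choice_rng = np.random.default_rng(choice_seed)
    datasets: dict[str, list[SubjectDataset]] = {c: [] for c in CONDITIONS}
    for i in range(n):
        sid = f"S{i + 1:02d}"
        for condition in CONDITIONS:
            sub_seed = int(choice_rng.integers(0, 2**31 - 1))
            pe = truth[i][condition].effective(m)
            truth[i][condition] = pe  # record effective (fixed -> 1) truth
            datasets[condition].append(
                simulate_subject_choices(
                    stimuli,
                    pe,
                    m,
                    sub_seed,
                    subject_id=sid,
                    condition=condition,
                    timeout_rate=design.timeout_rate,
                )
            )
    return CrossoverStudy(
        design=design,
        model_id=m.model_id,
        stimuli=stimuli,
        datasets=datasets,
        true_params=truth,
        condition_order=orders,
        seed=base,
    )
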