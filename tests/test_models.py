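"""Value functions, softmax rule, and choice likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gamblefit as gf
from gamblefit.models import dataset_negative_log_likelihood, trial_log_likelihood

from conftest import random_dataset


# -- power utility ------------------------------------------------------------


@pytest.mark.parametrize(
    "r, lam, expected",
    [(100, 1.0, 100.0), (100, 0.5, 10.0), (1, 0.73, 1.0)],
)
def test_power_utility_values(r, lam, expected):
    assert gf.power_utility(r, lam) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [(-1, 1), (0, 1), (1, 0), (1, -2)])
def test_power_utility_domain(bad):
    with pytest.raises(ValueError):
        gf.power_utility(*bad)


@pytest.mark.parametrize("lam, concave", [(0.5, True), (1.7, False)])
def test_power_utility_curvature(lam, concave):
    """Second differences are negative iff lam < 1 (concavity)."""
    r = np.linspace(0.5, 50, 400)
    u = gf.power_utility(r, lam)
    d2 = np.diff(u, 2)
    assert np.all(d2 < 0) if concave else np.all(d2 > 0)


# -- Prelec weighting ---------------------------------------------------------


@pytest.mark.parametrize("gam", [0.3, 0.65, 1.0, 1.7, 2.3])
def test_prelec_fixed_points(gam):
    """w(1) = 1 and w(1/e) = 1/e for every exponent."""
    assert gf.prelec_weight(1.0, gam) == pytest.approx(1.0, abs=1e-12)
    e_inv = math.exp(-1)
    assert gf.prelec_weight(e_inv, gam) == pytest.approx(e_inv, abs=1e-12)


def test_prelec_derived_value():
    # exp(-(ln 10)**0.65), frozen from a 50-digit symbolic evaluation
    assert gf.prelec_weight(0.1, 0.65) == pytest.approx(
        0.17912873725973016, abs=1e-12
    )


def test_prelec_identity_at_gamma_one():
    p = np.linspace(1e-6, 1.0, 1000)
    assert np.allclose(gf.prelec_weight(p, 1.0), p, atol=1e-12)


@pytest.mark.parametrize("gam", [0.3, 0.65, 1.0, 1.7, 2.3])
def test_prelec_monotone_and_crossing(gam):
    p = np.linspace(1e-4, 1.0, 2000)
    w = gf.prelec_weight(p, gam)
    assert np.all(np.diff(w) > 0)
    if gam != 1.0:
        # identity crossing only at p = 1/e (and the endpoint p = 1)
        sign = np.sign(w - p)
        interior = p < 1 - 1e-9
        crossings = np.nonzero(np.diff(sign[interior]) != 0)[0]
        assert len(crossings) == 1
        assert p[crossings[0]] == pytest.approx(math.exp(-1), abs=2e-3)


def test_prelec_inverse_s_shape():
    """gam < 1 overweights small and underweights large probabilities."""
    assert gf.prelec_weight(0.01, 0.5) > 0.01
    assert gf.prelec_weight(0.9, 0.5) < 0.9


@pytest.mark.parametrize("bad_p", [0.0, -0.1, 1.2])
def test_prelec_domain(bad_p):
    with pytest.raises(ValueError):
        gf.prelec_weight(bad_p, 0.6)


# -- option values ------------------------------------------------------------


def test_option_value_examples():
    ev = gf.option_value(gf.GambleOption(100, 0.5), gf.ParameterSet(), 1)
    assert ev == pytest.approx(50.0, abs=1e-12)
    v4 = gf.option_value(
        gf.GambleOption(100, 1.0), gf.ParameterSet(0.8, 0.6, 1.0), 4
    )
    assert v4 == pytest.approx(39.810717055349734, abs=1e-9)  # 100**0.8
    v4b = gf.option_value(
        gf.GambleOption(400, math.exp(-1)), gf.ParameterSet(0.5, 1.7, 1.0), 4
    )
    assert v4b == pytest.approx(7.357588823428846, abs=1e-9)  # 20 * e^-1


def test_option_value_unknown_model():
    with pytest.raises(ValueError):
        gf.option_value(gf.GambleOption(100, 0.5), gf.ParameterSet(), 7)


def test_model_nesting_to_machine_precision():
    """Model 4 with lam and/or gam pinned at 1 equals models 3/2/1."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        opt = gf.GambleOption(float(rng.uniform(1, 500)), float(rng.uniform(0.01, 1)))
        lam, gam = rng.uniform(0.2, 2.5, 2)
        p4 = gf.ParameterSet(lam, gam, 1.0)
        assert gf.option_value(opt, gf.ParameterSet(1.0, gam, 1.0), 4) == pytest.approx(
            gf.option_value(opt, p4, 3), abs=1e-12, rel=1e-12
        )
        assert gf.option_value(opt, gf.ParameterSet(lam, 1.0, 1.0), 4) == pytest.approx(
            gf.option_value(opt, p4, 2), abs=1e-12, rel=1e-12
        )
        assert gf.option_value(opt, gf.ParameterSet(1.0, 1.0, 1.0), 4) == pytest.approx(
            gf.option_value(opt, p4, 1), abs=1e-12, rel=1e-12
        )


# -- softmax ------------------------------------------------------------------


def test_choice_probability_examples():
    assert gf.choice_probability(3.7, 3.7, 5.0) == 0.5
    assert gf.choice_probability(10.0, -3.0, 0.0) == 0.5
    assert gf.choice_probability(math.log(3), 0.0, 1.0) == pytest.approx(0.75, abs=1e-12)


def test_choice_probability_stable_at_extreme_arguments():
    assert gf.choice_probability(700.0, 0.0, 1.0) == pytest.approx(1.0)
    assert gf.choice_probability(0.0, 700.0, 1.0) == pytest.approx(0.0, abs=1e-300)
    assert np.isfinite(gf.choice_probability(1e6, 0.0, 30.0))


def test_choice_probability_rejects_negative_beta():
    with pytest.raises(ValueError):
        gf.choice_probability(1.0, 0.0, -0.1)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    v_a=st.floats(-50, 50),
    v_b=st.floats(-50, 50),
    beta=st.floats(0, 30),
)
def test_choice_probability_complementary(v_a, v_b, beta):
    total = gf.choice_probability(v_a, v_b, beta) + gf.choice_probability(v_b, v_a, beta)
    assert total == pytest.approx(1.0, abs=1e-12)


# -- likelihood ---------------------------------------------------------------


def _equal_value_trial(choice="A"):
    return gf.GambleTrial(
        gf.GambleOption(100, 0.5), gf.GambleOption(50, 1.0), choice=choice
    )


def test_trial_log_likelihood_equal_values():
    ll = trial_log_likelihood(_equal_value_trial(), gf.ParameterSet(), 1)
    assert ll == pytest.approx(math.log(0.5), abs=1e-12)


def test_trial_log_likelihood_beta_zero():
    trial = gf.GambleTrial(
        gf.GambleOption(9000, 0.9), gf.GambleOption(100, 0.05), choice="B"
    )
    ll = trial_log_likelihood(trial, gf.ParameterSet(beta=0.0), 4)
    assert ll == pytest.approx(math.log(0.5), abs=1e-12)


def test_trial_log_likelihood_rejects_missing():
    with pytest.raises(ValueError):
        trial_log_likelihood(_equal_value_trial(choice="MISSING"), gf.ParameterSet(), 1)


def test_trial_log_likelihood_floored():
    """Huge beta and a dominated chosen option: floored, never -inf."""
    trial = gf.GambleTrial(
        gf.GambleOption(9000, 0.9), gf.GambleOption(100, 0.05), choice="B"
    )
    ll = trial_log_likelihood(trial, gf.ParameterSet(beta=1e6), 1)
    assert np.isfinite(ll)
    assert ll == pytest.approx(math.log(1e-12), rel=1e-6)


def test_dataset_nll_noise_floor():
    rng = np.random.default_rng(3)
    data = random_dataset(rng, n_trials=120)
    nll = dataset_negative_log_likelihood(data, gf.ParameterSet(beta=0.0), 4)
    assert nll == pytest.approx(120 * math.log(2), abs=1e-9)


def test_dataset_nll_matches_per_trial_loop():
    """Vectorised NLL equals the naive per-trial recomputation."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        data = random_dataset(rng, n_trials=int(rng.integers(5, 40)))
        params = gf.ParameterSet(*rng.uniform([0.2, 0.2, 0.1], [2.0, 2.0, 5.0]))
        model = int(rng.integers(1, 5))
        naive = -sum(
            trial_log_likelihood(t, params, model)
            for t in data.trials
            if t.choice in ("A", "B")
        )
        fast = dataset_negative_log_likelihood(data, params, model)
        assert fast == pytest.approx(naive, abs=1e-10)


def test_dataset_nll_skips_missing_trials():
    rng = np.random.default_rng(5)
    data = random_dataset(rng, n_trials=10)
    with_missing = gf.SubjectDataset(
        "S",
        "neutral",
        data.trials
        + [
            gf.GambleTrial(
                gf.GambleOption(500, 0.3), gf.GambleOption(200, 0.9), "MISSING"
            )
        ],
    )
    params = gf.ParameterSet(0.8, 0.7, 2.0)
    assert dataset_negative_log_likelihood(
        with_missing, params, 4
    ) == pytest.approx(dataset_negative_log_likelihood(data, params, 4), abs=1e-12)


def test_dataset_requires_usable_trial():
    with pytest.raises(ValueError):
        gf.SubjectDataset(
            "S",
            "neutral",
            [
                gf.GambleTrial(
                    gf.GambleOption(500, 0.3), gf.GambleOption(200, 0.9), "MISSING"
                )
            ],
        )


def test_nll_at_truth_beats_perturbed_parameters():
    """Averaged over simulated datasets, the generating parameters score
    at least as well as +/-50% perturbations of themselves."""
    rng = np.random.default_rng(42)
    design = gf.StudyDesign(n_subjects=1, trials_per_condition=240)
    stimuli = gf.generate_gamble_set(design, seed=9)
    truth = gf.ParameterSet(0.9, 0.7, 2.0)
    deltas = []
    for k in range(50):
        data = gf.simulate_subject_choices(stimuli, truth, 4, seed=1000 + k)
        nll_true = dataset_negative_log_likelihood(data, truth, 4)
        factor = 1.5 if k % 2 else 0.5
        perturbed = gf.ParameterSet(
            truth.lam * factor, truth.gam * factor, truth.beta * factor
        )
        deltas.append(
            dataset_negative_log_likelihood(data, perturbed, 4) - nll_true
        )
    assert np.mean(deltas) > 0


def test_model_spec_free_param_counts():
    assert [gf.get_model(i).n_free_params for i in (1, 2, 3, 4)] == [1, 2, 2, 3]
    assert gf.get_model(4).free_names == ("lam", "gam", "beta")


def test_invalid_domain_types():
    with pytest.raises(ValueError):
        gf.GambleOption(-5, 0.5)
    with pytest.raises(ValueError):
        gf.GambleOption(100, 1.5)
    with pytest.raises(ValueError):
        gf.GambleTrial(gf.GambleOption(100, 0.5), gf.GambleOption(100, 0.5))
    with pytest.raises(ValueError):
        gf.ParameterSet(lam=-1)
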