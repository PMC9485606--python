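import numpy as np
import pytest

import gamblefit as gf


@pytest.fixture(scope="session")
def small_design() -> gf.StudyDesign:
    return gf.StudyDesign(n_subjects=8, trials_per_condition=60)


@pytest.fixture(scope="session")
def default_pop() -> gf.PopulationSpec:
    return gf.PopulationSpec()


@pytest.fixture(scope="session")
def small_study(small_design, default_pop) -> gf.CrossoverStudy:
    """8 subjects x 2 conditions x 60 trials simulated from model 4."""
    return gf.simulate_crossover_study(small_design, default_pop, 4, seed=2024)


def random_dataset(rng: np.random.Generator, n_trials: int = 20,
                   subject_id: str = "S", condition: str = "neutral",
                   params: gf.ParameterSet | None = None,
                   model: int = 4) -> gf.SubjectDataset:
    """Small random dataset with random (not model-generated) choices."""
    trials = []
    for i in range(n_trials):
        pa, pb = rng.choice([0.05, 0.1, 0.3, 0.5, 0.8, 0.9, 1.0], 2)
        trials.append(
            gf.GambleTrial(
                gf.GambleOption(float(rng.uniform(100, 10_000)), float(pa)),
                gf.GambleOption(float(rng.uniform(100, 10_000)), float(pb)),
                choice="A" if rng.random() < 0.5 else "B",
                session=1,
            )
        )
    return gf.SubjectDataset(subject_id, condition, trials)
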