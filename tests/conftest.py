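import numpy as np
import pytest

from crtsim import PerturbationSpec, TaskSpec, run_trial


@pytest.fixture(scope="session")
def trial_bank():
    """Session-wide cache of full 8 s trials keyed by condition.

    Acceptance tests share trials through this cache so each (task,
    perturbation, strength, seed) cell is simulated exactly once.
    """
    cache: dict = {}

    def get(task: str = "smooth_pursuit", kind: str = "none",
            strength: float = 1.0, seed: int = 0):
        key = (task, kind, strength, seed)
        if key not in cache:
            spec = (
                TaskSpec.pursuit()
                if task == "smooth_pursuit"
                else TaskSpec.fixation()
            )
            cache[key] = run_trial(spec, PerturbationSpec(kind, strength), seed=seed)
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
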