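import warnings

import numpy as np
import pytest

import pgropt


@pytest.fixture(scope="session")
def wallflower():
    return pgropt.load_wallflower()


@pytest.fixture(scope="session")
def fitted_models(wallflower):
    """One set of trained surrogates (seed 0) shared across read-only tests."""
    idx = pgropt.split(wallflower, 0.8, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models, reports = pgropt.fit_all_outputs(
            wallflower, pgropt.TrainingConfig(seed=0), idx
        )
    return {"models": models, "reports": reports, "split": idx}


@pytest.fixture(scope="session")
def chosen_hidden_sizes(wallflower):
    """Per-output hidden sizes from the trial-and-error search (run once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chosen, _ = pgropt.select_hidden_size(wallflower)
    return chosen


@pytest.fixture(scope="session")
def multi_seed_fits(wallflower, chosen_hidden_sizes):
    """Fits over 10 seeds: the repeated-seed protocol used for headline medians."""
    runs = []
    for s in range(10):
        idx = pgropt.split(wallflower, 0.8, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models, reports = pgropt.fit_all_outputs(
                wallflower, pgropt.TrainingConfig(seed=s), idx,
                hidden_sizes=chosen_hidden_sizes,
            )
        runs.append({"seed": s, "models": models, "reports": reports, "split": idx})
    return runs


def rng(seed=0):
    return np.random.default_rng(seed)
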