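import numpy as np
import pandas as pd
import pytest

from priorweight import (
    ModelVariant,
    ObserverParams,
    TaskConfig,
    generate_experiment,
    simulate_responses,
)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig(seed=11)


@pytest.fixture(scope="session")
def experiment(default_config):
    return generate_experiment(default_config)


@pytest.fixture(scope="session")
def typical_params():
    """A parameter set exhibiting the expected group-level pattern."""
    return ObserverParams(
        v_bar_L=-0.1, v_bar_H=1.0, a_g=0.5, omega_L=1.5, omega_H=2.5, b_g=0.4
    )


@pytest.fixture(scope="session")
def subject(experiment, typical_params):
    """One synthetic subject: (trials, responses) under the full model."""
    responses = simulate_responses(
        experiment, typical_params, ModelVariant.FULL, np.random.default_rng(7)
    )
    return experiment, responses


def make_trials(mu_bar, var_cond, g1, g2, interval=10.0):
    """Hand-built minimal trial table for arithmetic fixtures."""
    mu_bar = np.asarray(mu_bar, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n = len(mu_bar)
    mu_g = (g1 + g2) / 2.0
    return pd.DataFrame({
        "session_index": 0,
        "block_index": 0,
        "trial_index": np.arange(n),
        "mu_bar": mu_bar.astype(int),
        "var_cond": list(var_cond),
        "mu_true_raw": mu_bar,
        "mu_true": mu_bar.astype(int),
        "g1_raw": g1, "g1": g1.astype(int),
        "g2_raw": g2, "g2": g2.astype(int),
        "mu_g": mu_g,
        "v_g": np.abs(g1 - g2),
        "pe": np.abs(mu_bar - mu_g),
        "onset": np.arange(n) * interval,
    })


def make_responses(trials, r, rt=2.0):
    r = np.asarray(r)
    return pd.DataFrame({
        "session_index": trials["session_index"].to_numpy(),
        "trial_index": trials["trial_index"].to_numpy(),
        "onset": trials["onset"].to_numpy(),
        "R": r,
        "rt": np.full(len(trials), rt, dtype=float),
    })
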