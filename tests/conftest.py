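"""Shared fixtures: small deterministic survival simulators."""

import numpy as np
import pandas as pd
import pytest

from dietcal.simulate import FoodDistribution, SimulationConfig


def weibull_survival_frame(
    n=500,
    seed=0,
    beta_x=0.0,
    beta_z=0.0,
    shape=9.0,
    scale=92.0,
    entry_range=(40.0, 70.0),
    followup=(8.0, 14.0),
    all_events=False,
):
    """Left-truncated Weibull survival with one continuous and one binary
    covariate; the closed form makes it an oracle for the Cox engine."""
    rng = np.random.default_rng(seed)
    entry = rng.uniform(*entry_range, n)
    x = rng.normal(size=n)
    z = rng.binomial(1, 0.5, n).astype(float)
    theta = np.exp(beta_x * x + beta_z * z)
    u = rng.random(n)
    T = scale * ((entry / scale) ** shape - np.log(u) / theta) ** (1.0 / shape)
    if all_events:
        exit_age, event = T, np.ones(n, bool)
    else:
        C = entry + rng.uniform(*followup, n)
        exit_age, event = np.minimum(T, C), T <= C
    return pd.DataFrame(
        {"entry_age": entry, "exit_age": exit_age, "event": event, "x": x, "z": z}
    )


@pytest.fixture
def survival_frame():
    return weibull_survival_frame(n=200, seed=3, beta_x=0.4, beta_z=-0.3)


def attenuation_config(seed, n=20000, reliability=0.5, hr90=1.5, x90=46.5):
    """No-zero-inflation cohort with classical FFQ error at the given
    reliability on the model (log1p) scale and a true 90th-vs-0 contrast
    hazard ratio of ``hr90``."""
    from dietcal.simulate import log1p_scale_sd

    red = FoodDistribution(0.0, 2.3, 1.1)
    s = log1p_scale_sd(red)
    ffq_sd = s * np.sqrt(1.0 / reliability - 1.0)
    return SimulationConfig(
        n_subjects=n,
        seed=seed,
        exposure_distribution={
            "unprocessed_red": red,
            "processed": FoodDistribution(0.0, 0.75, 1.3),
        },
        exposure_correlation=0.3,
        ffq_error={"unprocessed_red": ffq_sd, "processed": 1.0},
        recall_error=0.5,
        true_log_hr={"unprocessed_red": np.log(hr90) / np.log1p(x90)},
    )
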