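"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from causalddm.synthetic import (default_config, generate_task_data,
                                 generate_traits, recovery_config)


@pytest.fixture(scope="session")
def tiny_fit_data():
    """6 subjects, 2 clusters, 3 lags, 40 trials/lag: quick MCMC fixture."""
    cfg = recovery_config(n_subjects=6, trials_per_lag=40, seed=11)
    trials, truth = generate_task_data(cfg)
    clusters = trials.groupby("subject_id")["cluster_truth"].first().rename("cluster")
    return cfg, trials, truth, clusters


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down study: 33 subjects across the three trait clusters."""
    cfg = default_config(n_subjects_per_cluster=(10, 12, 11), seed=7)
    trials, truth = generate_task_data(cfg)
    traits = generate_traits(cfg)
    return cfg, trials, truth, traits


@pytest.fixture(scope="session")
def traits_150():
    cfg = default_config(seed=5)
    return cfg, generate_traits(cfg)
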