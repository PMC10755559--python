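import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import prlkit as pk

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_task() -> pk.TaskConfig:
    return pk.TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject two-group cohort from the winning model, one block."""
    spec = pk.CohortSpec(group_sizes={"control": 3, "gambling": 3},
                         rng_seed=42)
    trials, truth = pk.generate_cohort(spec, pk.TaskConfig(n_blocks=1))
    return trials, truth


def make_params(alpha=0.4, alpha_pun=None, beta=3.0, kappa_stim=0.0,
                kappa_side=0.0) -> pk.ParameterSet:
    return pk.ParameterSet(alpha, alpha if alpha_pun is None else alpha_pun,
                           beta, kappa_stim, kappa_side)


@pytest.fixture(scope="session")
def winning_model_cohort():
    """12-subject cohort (4 per group, full 3-block task) from model 6."""
    spec = pk.CohortSpec(group_sizes={"control": 4, "gambling": 4, "cud": 4},
                         rng_seed=11)
    return pk.generate_cohort(spec, pk.TaskConfig())


@pytest.fixture(scope="session")
def winning_model_fit(winning_model_cohort):
    """Full-length hierarchical fit of model 6 (4 chains, 1000+1000)."""
    trials, _ = winning_model_cohort
    est = pk.HierarchicalRLModel(
        model_id=6, mcmc=pk.McmcConfig(chains=4, warmup=1000, samples=1000,
                                       seed=5))
    return est.fit(trials)
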