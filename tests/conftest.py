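import logging

import numpy as np
import pandas as pd
import pytest

from taskpotency.config import SimConfig
from taskpotency import simulate as sim

logging.getLogger("taskpotency").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale simulator configuration used across tests."""
    return SimConfig(n_autism=12, n_td=12, n_sites=2, n_regions=40,
                     n_networks=4, n_timepoints=300)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(cohort, ground truth) for the desk-scale configuration."""
    cohort = sim.generate_cohort(small_cfg, 11)
    gt = sim.generate_ground_truth(small_cfg, 11)
    return cohort, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def null_edge_cohort():
    """TD-only potency edges with age/sex structure and unit Gaussian noise."""
    tasks, cov, truth = sim.simulate_potency_edges(
        n_td=200, n_autism=0, n_edges=800, seed=5)
    return tasks["task0"], cov, truth
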