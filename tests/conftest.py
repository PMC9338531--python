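import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import concordmap as cm
from concordmap import pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """One small default-structured cohort shared by read-only tests."""
    cfg = cm.SynthConfig(seed=7, n_genes=600, n_events=40,
                         n_per_group={"normal": 8, "inflammation": 8, "tumor": 16})
    cohort, table, truth = cm.simulate_cohort(cfg)
    return cfg, cohort, table, truth


@pytest.fixture(scope="session")
def prepared_small_cohort(small_cohort):
    cfg, cohort, table, truth = small_cohort
    return cfg, pipeline.prepare_cohort(cohort), table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
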