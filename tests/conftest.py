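import numpy as np
import pandas as pd
import pytest

from spcprof.core import RunInfo, RunList, SpectralCountMatrix
from spcprof.simulate import SimulationConfig, simulate_dataset


def make_matrix(data, cohorts, run_ids=None, subjects=None):
    """Small SpectralCountMatrix from a dict protein -> counts list."""
    counts = pd.DataFrame.from_dict(data, orient="index")
    run_ids = run_ids or [f"r{i+1}" for i in range(counts.shape[1])]
    subjects = subjects or run_ids
    counts.columns = run_ids
    runs = [RunInfo(r, s, c) for r, s, c in zip(run_ids, subjects, cohorts)]
    return SpectralCountMatrix(counts, runs)


def make_run(run_id, entries, subject=None, cohort="Wt", kind="technical"):
    return RunList(run_id, subject or run_id, cohort, kind, dict(entries))


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(n_proteins=600, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
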