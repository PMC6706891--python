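import logging

import numpy as np
import pytest

from beem import EMConfig, SimulationConfig, run_em, simulate_dataset
from beem.evaluate import run_benchmark
from beem.preprocess import preprocess

# the EM and preprocessing emit deliberate WARNINGs on small test inputs;
# keep the test log readable
logging.getLogger("beem").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic community used across unit tests."""
    return simulate_dataset(
        SimulationConfig(n_species=10, n_replicates=6, n_timepoints=25, time_span=24.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_pre(small_dataset):
    ds = small_dataset
    return preprocess(ds.counts, ds.times, species_ids=ds.params_true.species_ids)


@pytest.fixture(scope="session")
def benchmark_results():
    """The scaling-condition comparison at desk scale: 5 simulated datasets
    of 10 species, 15 replicates of 30 time points each."""
    cfg = SimulationConfig(
        n_species=10, n_replicates=15, n_timepoints=30, time_span=29.0
    )
    return run_benchmark(
        cfg,
        conditions=("noise-free", "RA", "qPCR_rep1", "qPCR_rep3", "BEEM"),
        n_sims=5,
        seed=1,
    )


@pytest.fixture(scope="session")
def em_biomass_runs():
    """Three full EM runs on 10-species, 20-replicate, 30-time-point data."""
    out = []
    for k in range(3):
        seed = int(np.random.SeedSequence([1, 100 + k]).generate_state(1)[0] % (2**31))
        ds = simulate_dataset(
            SimulationConfig(n_species=10, n_replicates=20, n_timepoints=30,
                             time_span=29.0, seed=seed)
        )
        pre = preprocess(ds.counts, ds.times, species_ids=ds.params_true.species_ids)
        res = run_em(pre, EMConfig())
        out.append((ds, res))
    return out
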