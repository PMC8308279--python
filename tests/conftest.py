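import numpy as np
import pytest

from crconsensus import ProbePairSet, SimConfig, compute_call_table, simulate
from crconsensus.consensus import direction_matrix_from_calls


def make_pair_set(pm, mm, probe="probe_1", chip="chip_1"):
    return ProbePairSet(
        probe_set_id=probe,
        pm=np.asarray(pm, dtype=float),
        mm=np.asarray(mm, dtype=float),
        chip_id=chip,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic study shared across tests (low noise, seed 1)."""
    config = SimConfig(n_probesets=150, noise_sd=0.05, seed=1)
    return config, simulate(config)


@pytest.fixture(scope="session")
def small_sim_matrix(small_sim):
    """Direction matrix computed once from the shared synthetic study."""
    _, result = small_sim
    calls = compute_call_table(result.intensities, result.design)
    return calls, direction_matrix_from_calls(calls)
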