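import numpy as np
import pytest

from xsmm import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_truth():
    return synth.SimulationTruth(seed=11)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """A small zero-noise experiment: the pipeline must recover delta exactly."""
    truth = synth.SimulationTruth(noise_sd=0.0, seed=7)
    consensus, design_a, design_b, ledger = synth.generate_designs(
        truth, n_probesets=120, probes_per_set=5, consensus_length=60
    )
    matrix_a, matrix_b = synth.simulate_intensities(truth, ledger)
    return {
        "truth": truth,
        "consensus": consensus,
        "design_a": design_a,
        "design_b": design_b,
        "ledger": ledger,
        "matrix_a": matrix_a,
        "matrix_b": matrix_b,
    }
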