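import numpy as np
import pytest

from clockshift.deconvolution import estimate_fractions_rpc, intersect_probes
from clockshift.evaluation import evaluate_schemes
from clockshift.synthetic_data import (
    SyntheticCohortConfig,
    simulate_pipeline_inputs,
)

#: one fixed cohort seed shared by the slower end-to-end fixtures
COHORT_SEED = 0


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort, stand-in clock and raw predictions."""
    return simulate_pipeline_inputs(SyntheticCohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_fractions(default_sim):
    """RPC-estimated fractions for the default cohort."""
    beta_i, ref_i = intersect_probes(default_sim["beta"], default_sim["reference"])
    return estimate_fractions_rpc(beta_i, ref_i)


@pytest.fixture(scope="session")
def default_report(default_sim, default_fractions):
    """Full scheme-comparison report on the default cohort (shared: slow)."""
    return evaluate_schemes(
        default_sim["predictions"],
        default_sim["annotations"],
        default_fractions,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
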