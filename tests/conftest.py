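import numpy as np
import pytest

from tracedecomp import (
    Mixture,
    TraceNoiseModel,
    apply_indel,
    example_reference,
    simulate_trace,
)


@pytest.fixture(scope="session")
def reference():
    return example_reference()


@pytest.fixture(scope="session")
def wt_allele(reference):
    return apply_indel(reference, 0)


@pytest.fixture(scope="session")
def noiseless():
    return TraceNoiseModel(noise_sd=0.0, crosstalk=0.0, decay_rate=0.0)


@pytest.fixture(scope="session")
def control_trace(reference, wt_allele, noiseless):
    """Noiseless wild-type control chromatogram."""
    return simulate_trace(Mixture(components=((wt_allele, 1.0),)), reference, noiseless)


@pytest.fixture(scope="session")
def noisy_control(reference, wt_allele):
    """Control rendered under the default noise model."""
    return simulate_trace(
        Mixture(components=((wt_allele, 1.0),)),
        reference,
        TraceNoiseModel(seed=987654),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
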