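import numpy as np
import pytest

from fluxgp import (
    KernelSpec,
    PriorSpec,
    TimeSeriesSet,
    gen_oscillators,
    map_estimate,
    standard_two_output_spec,
)


def random_kernel(rng, source="s", output="a") -> KernelSpec:
    """Kernel with amplitude and inverse width in a moderate range."""
    return KernelSpec(
        amplitude=float(np.exp(rng.uniform(-1.2, 1.2))),
        inv_width=float(np.exp(rng.uniform(-1.2, 1.2))),
        source_id=source,
        output_id=output,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def oscillator_sim():
    return gen_oscillators(seed=3)


@pytest.fixture(scope="session")
def small_data():
    """Tiny two-output dataset with unequal, irregular sampling."""
    return TimeSeriesSet.from_arrays({
        "z1": ([0.0, 0.7, 1.5, 2.4, 3.3], [0.1, 0.8, 1.0, 0.4, -0.5]),
        "z2": ([0.2, 1.1, 2.9], [0.5, 0.9, -0.2]),
    })


@pytest.fixture(scope="session")
def oscillator_fit(oscillator_sim):
    """A cached MAP fit of the two-output model to the oscillator data."""
    spec = standard_two_output_spec()
    priors = PriorSpec.from_data(spec, oscillator_sim.observations)
    fit = map_estimate(spec, priors, oscillator_sim.observations,
                       n_starts=4, seed=5)
    return spec, priors, fit
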