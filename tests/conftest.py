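import numpy as np
import pytest

import repeatdepth as rd


@pytest.fixture(scope="session")
def toy_config():
    """Small, fast geometry: 500 kb genome, 5 kb unit, 10 true copies."""
    return rd.SimConfig(
        seed=7,
        true_copy_number=10,
        genome_length=500_000,
        repeat_unit_length=5_000,
        n_read_pairs=20_000,
    )


@pytest.fixture(scope="session")
def toy_reference(toy_config):
    return rd.build_reference(toy_config)


@pytest.fixture(scope="session")
def toy_simulation(toy_reference, toy_config):
    return rd.simulate_reads(toy_reference, toy_config)


@pytest.fixture(scope="session")
def default_reference():
    """The default study geometry (8 Mb genome, 200 bp unit) shared across
    read-simulation tests; the GC index cache makes reuse cheap."""
    return rd.build_reference(rd.SimConfig(seed=0, true_copy_number=100))


def binomial_3sd(p, n):
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
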