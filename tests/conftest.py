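import logging

import pytest

from plexdiff import SimulationConfig, simulate_study

logging.getLogger("plexdiff").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic region reused by the fast unit tests."""
    config = SimulationConfig(
        seed=42,
        n_proteins=8,
        peptides_per_protein=(1, 2),
        spectra_per_peptide=(1, 2),
        fraction_differential=0.25,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def default_study():
    """The default desk-scale study conditions."""
    return simulate_study(SimulationConfig(seed=7))
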