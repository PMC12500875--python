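from fractions import Fraction

import pytest

from enviropinet.dataio import biofilter_repeating, biofilter_specs
from enviropinet.dimensions import VariableSpec, construct_pi_basis
from enviropinet.models import FFNNConfig
from enviropinet.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def specs():
    return biofilter_specs()


@pytest.fixture(scope="session")
def repeating():
    return biofilter_repeating()


@pytest.fixture(scope="session")
def basis(specs, repeating):
    return construct_pi_basis(specs, repeating=repeating)


@pytest.fixture(scope="session")
def table_noisy():
    """Default three-study table (175/26/116 rows), sigma = 0.05."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def table_clean():
    """Noiseless table: log(EC/IC) is exactly affine in the log pi-groups."""
    return generate(SyntheticConfig(sigma=0.0, seed=12))


@pytest.fixture()
def fast_ffnn():
    """Small network protocol for structure/determinism tests."""
    return FFNNConfig(
        hidden=(16, 8), max_epochs=120, patience=15, n_folds=3, seeds=(0,)
    )


def make_spec(symbol, role="independent", **dims):
    return VariableSpec(
        symbol=symbol,
        dimensions={d: Fraction(e) for d, e in dims.items()},
        role=role,
    )
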