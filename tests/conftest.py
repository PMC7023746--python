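import numpy as np
import pytest

from subclonesig import (
    Catalog,
    LineageSimConfig,
    flat_signature,
    make_reference,
    peaked_signature,
    simulate_experiment,
)
from subclonesig.channels import sbs96_scheme


@pytest.fixture(scope="session")
def sbs96():
    return sbs96_scheme()


@pytest.fixture(scope="session")
def reference():
    """A 200 kb random reference shared across tests."""
    return make_reference(200_000, seed=20240917)


@pytest.fixture(scope="session")
def clean_experiment():
    """One seeded clean two-parent experiment with a treatment arm."""
    return simulate_experiment(LineageSimConfig(seed=77))


def multinomial_catalog(scheme, samples, parts, seed):
    """Catalog whose columns are sums of multinomial draws.

    ``parts`` is a list of (signature, burden) pairs added per sample.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(scheme), len(samples)), dtype=int)
    for j in range(len(samples)):
        for sig, burden in parts:
            if burden > 0:
                counts[:, j] += rng.multinomial(burden, sig.weights)
    return Catalog(scheme, list(samples), counts)


@pytest.fixture(scope="session")
def background_sig(sbs96):
    return flat_signature(sbs96)


@pytest.fixture(scope="session")
def treatment_sig(sbs96):
    return peaked_signature(5, seed=42, scheme=sbs96)
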