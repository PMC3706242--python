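import numpy as np
import pytest

from celiacqsp import (
    PatientVariant,
    build_network,
    compute_references,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def patient_net(params):
    return build_network(params, PatientVariant.PATIENT)


@pytest.fixture(scope="session")
def healthy_net(params):
    return build_network(params, PatientVariant.HEALTHY)


@pytest.fixture(scope="session")
def refs(params):
    """Normalisation references (healthy + untreated gluten steady states)."""
    return compute_references(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130705)


def random_state(net, rng, scale=2.0):
    """A random non-negative state roughly on the model's natural scales."""
    return scale * rng.random(net.n_species) * np.array(
        [10.0 if s == "Glut_lum" else 1.0 for s in net.species]
    )
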