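import numpy as np
import pytest

from fluorosig import synthetic_data as syn


@pytest.fixture(scope="session")
def signature_set():
    """Three planted signatures: sig17like, flat, one random profile."""
    return syn.make_signature_set(seed=0, n_random=1)


@pytest.fixture()
def toy_reference():
    """Tiny in-memory contigs for context extraction tests."""
    return {"1": "ACGTACGT", "toy": "AACTTGGACTG"}


@pytest.fixture(scope="session")
def planted_catalog(signature_set):
    """50-sample catalog of 5,000 mutations each from Dirichlet
    mixtures of the three planted signatures, with the mixing truth."""
    rng = np.random.default_rng(11)
    exposures = rng.dirichlet(np.ones(3), 50).T * 5000
    catalog = syn.sample_catalog(signature_set, exposures, seed=12)
    return catalog, exposures
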