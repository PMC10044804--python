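"""Shared fixtures: small simulated genomes with known ground truth."""

import numpy as np
import pytest

from evotrace.io import GenomeRecord
from evotrace.pipeline import fixture_params
from evotrace.simulate import generate_ancestor, evolve_lineage, simulate_sibling_pair


@pytest.fixture(scope="session")
def tiny_params():
    return fixture_params("tiny", 1)


@pytest.fixture(scope="session")
def tiny_ancestor(tiny_params):
    return generate_ancestor(tiny_params)


@pytest.fixture(scope="session")
def tiny_lineage(tiny_params, tiny_ancestor):
    ancestor, features = tiny_ancestor
    genome, truth = evolve_lineage(ancestor, features, tiny_params,
                                   tiny_params.days_total, seed=1001)
    return genome, truth


@pytest.fixture(scope="session")
def tiny_siblings(tiny_params, tiny_ancestor):
    ancestor, features = tiny_ancestor
    return simulate_sibling_pair(tiny_params, ancestor, features)


@pytest.fixture(scope="session")
def is_reference(tiny_params):
    return GenomeRecord(id="ISsyn1", sequence=tiny_params.is_sequence)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230327)


def random_sequence(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
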