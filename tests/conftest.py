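import warnings

import numpy as np
import pytest

from tecurate.models import Order, ProfileRole
from tecurate.search import SubjectIndex
from tecurate.simulate import (
    FamilySpec,
    build_genome,
    make_family,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def dataset():
    """The standard fixed-seed simulation scenario (expensive; shared)."""
    return simulate_dataset(seed=42)


@pytest.fixture(scope="session")
def genome_index(dataset):
    return SubjectIndex(dataset.genome)


@pytest.fixture(scope="session")
def ltr_family():
    """A single 2 kb LTR family with 20 copies at 5% divergence."""
    spec = FamilySpec(
        "fam1",
        Order.LTR,
        2000,
        ltr_length=300,
        planted_domains=(ProfileRole.RT, ProfileRole.INT),
    )
    ancestor = make_family(spec, seed=7)
    genome, truth = build_genome(
        {"fam1": ancestor}, {"fam1": 20}, {"fam1": 0.05},
        background_bp=100_000, seed=11,
    )
    return spec, ancestor, genome, truth


@pytest.fixture(scope="session")
def ltr_genome_index(ltr_family):
    _, _, genome, _ = ltr_family
    return SubjectIndex(genome)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
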