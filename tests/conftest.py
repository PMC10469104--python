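import numpy as np
import pytest

from pepspace import (
    DescriptorCalculator,
    FamilySpec,
    MetricSpec,
    PeptideSet,
    Peptide,
    make_dataset,
    pairwise_similarity,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Two well-separated families plus background, fixed seed."""
    specs = [
        FamilySpec(seed_length=24, n_members=12, substitution_rate=0.05, label="famA"),
        FamilySpec(seed_length=24, n_members=12, substitution_rate=0.05, label="famB"),
    ]
    peptides, labels = make_dataset(specs, n_background=10, rng_seed=11)
    return peptides, labels


@pytest.fixture(scope="session")
def descriptor_setup(small_dataset):
    peptides, _ = small_dataset
    calc = DescriptorCalculator()
    matrix = calc.fit_transform(peptides).normalized()
    return peptides, calc, matrix


@pytest.fixture(scope="session")
def similarity(descriptor_setup):
    _, _, matrix = descriptor_setup
    return pairwise_similarity(matrix, MetricSpec("euclidean", "reciprocal"))


@pytest.fixture
def toy_peptides():
    return PeptideSet(
        [
            Peptide("p1", "ACDEFGHIK"),
            Peptide("p2", "KKKKKKKKK"),
            Peptide("p3", "ACDEFGHIL"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
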