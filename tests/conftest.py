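import numpy as np
import pytest

from aptaselect import (
    FeatureSchema,
    SyntheticSpec,
    assemble_dataset,
    filter_descriptors,
    generate_study,
)
from aptaselect.encoding import COMPOUND_CATEGORIES


def build_dataset(study):
    """Assemble the labeled matrix of a synthetic study."""
    compounds, retained = filter_descriptors(list(study.compounds))
    schema = FeatureSchema.build(retained, study.category_map)
    return assemble_dataset(study.pairs, study.aptamers, compounds, schema)


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced synthetic study: small grid, few pairs."""
    return SyntheticSpec(
        n_compounds=60,
        n_aptamers=10,
        n_pairs=90,
        n_informative=3,
        n_redundant=2,
        n_noise=7,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_study(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_study):
    return build_dataset(small_study)


@pytest.fixture(scope="session")
def default_study():
    """One default-parameter study (450 pairs, 46 features)."""
    return generate_study(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_dataset(default_study):
    return build_dataset(default_study)


def schema_with_descriptors(n: int) -> FeatureSchema:
    """A schema with n synthetic compound descriptors, categories round-robin."""
    names = [f"d{i:03d}" for i in range(n)]
    cmap = {name: COMPOUND_CATEGORIES[i % 5] for i, name in enumerate(names)}
    return FeatureSchema.build(names, cmap)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
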