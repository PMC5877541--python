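import pytest

from mitofeatures.data import load_reference_feature_table
from mitofeatures.synthetic import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def reference_table():
    """The published 37-gene + CR organization table."""
    return load_reference_feature_table()


@pytest.fixture(scope="session")
def default_genome():
    """A synthetic genome realizing the published layout (seed 42)."""
    return generate_genome(GenomeSpec.from_reference(seed=42))
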