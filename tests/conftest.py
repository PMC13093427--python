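import pytest

from mitocomp.synthetic_data import GeneratorParams, generate_mitogenome
from mitocomp.tables import load_printed_features


@pytest.fixture(scope="session")
def borneensis():
    """Published OR466573 gene boundaries (16,943 bp)."""
    return load_printed_features("OR466573")


@pytest.fixture(scope="session")
def lopis():
    """Published OQ446559 gene boundaries (16,176 bp)."""
    return load_printed_features("OQ446559")


@pytest.fixture(scope="session")
def synthetic_record():
    """One generated mitogenome on the default (published) layout."""
    return generate_mitogenome(GeneratorParams(seed=1))
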