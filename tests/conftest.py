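import numpy as np
import pytest

from protsar.chemio import read_dataset
from protsar.descriptors import DescriptorPanel
from protsar.pipeline import clinical_drugs_path
from protsar.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def drug_records():
    """The six clinical-inhibitor fixture records."""
    return read_dataset(clinical_drugs_path())


@pytest.fixture(scope="session")
def drug_panel(drug_records):
    return DescriptorPanel().fit(drug_records).transform(drug_records)


@pytest.fixture(scope="session")
def drug_by_id(drug_records):
    return {r.id: r for r in drug_records}


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One small seeded synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(n_compounds=150, seed=11))


@pytest.fixture(scope="session")
def synthetic_full():
    """A full-size (680) seeded synthetic dataset."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
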