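import numpy as np
import pytest

from smitox import (ChemicalRecord, GeneratorConfig, SmilesDictionary,
                    generate_dataset, label_binary)


@pytest.fixture(scope="session")
def example_dictionary() -> SmilesDictionary:
    """The six-character acrylonitrile example dictionary."""
    return SmilesDictionary({"C": 1, "=": 2, "(": 3, ")": 4, "#": 5, "N": 6})


@pytest.fixture(scope="session")
def ten_records() -> list[ChemicalRecord]:
    """Ten records with known route/species tags for filter enumeration."""
    tags = [
        ("oral", "rat"), ("oral", "mouse"), ("iv", "rat"), ("oral", "rabbit"),
        ("ip", "mouse"), ("oral", "rat"), ("subcutaneous", "rat"),
        ("oral", "mouse"), ("iv", "mouse"), ("oral", "rat"),
    ]
    return [
        ChemicalRecord(id=f"r{i}", smiles="CCO", ld50=100.0 * (i + 1),
                       route=route, species=species)
        for i, (route, species) in enumerate(tags)
    ]


@pytest.fixture(scope="session")
def planted_config() -> GeneratorConfig:
    """Default planted-signal study conditions (strong nitrile effect)."""
    return GeneratorConfig(n=2000, motif_effect=-1.0, seed=11)


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    records = generate_dataset(planted_config)
    return label_binary(records, cutoff=planted_config.median_ld50())


def descriptor_matrix(dataset) -> np.ndarray:
    return np.vstack([r.descriptors for r in dataset.records])
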