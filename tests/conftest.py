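import numpy as np
import pandas as pd
import pytest

from hostscent import synthetic, preprocess, sharedness


@pytest.fixture(scope="session")
def dataset():
    """Default 28-species volatilome used across the suite."""
    return synthetic.generate_volatilome(synthetic.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def processed(dataset):
    return preprocess.preprocess(dataset)


@pytest.fixture(scope="session")
def species_labels(dataset, processed):
    return (dataset.samples.set_index("sample_id")["species_id"]
            .reindex(processed.detection.index))


@pytest.fixture(scope="session")
def proportions(processed, species_labels):
    return sharedness.detection_proportions(processed.detection,
                                            species_labels)


@pytest.fixture(scope="session")
def shared28(proportions):
    return sharedness.sharedness_table(proportions)["sharedness_28"]


@pytest.fixture(scope="session")
def covariates(dataset):
    return dataset.compound_frame()
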