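import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lncsig import SimConfig, generate_dataset, normalize_dataset
from lncsig.pipeline import contrast_labels

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_dataset():
    """Default study-design dataset: 21 benign / 30 malignant / 22 controls,
    28 probes, 8 planted malignancy probes at +1 log2."""
    dataset, truth = generate_dataset(SimConfig(seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def norm_case_matrix(sim_dataset):
    """Normalized log2 matrix of the IPMN cases plus malignant labels."""
    dataset, _ = sim_dataset
    labels = contrast_labels(dataset, "malignant_benign")
    sub = dataset.subset(labels.index)
    norm = normalize_dataset(sub)
    return norm.data, labels.to_numpy()
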