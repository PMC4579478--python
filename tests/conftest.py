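"""Shared fixtures: a small, fast synthetic design and generated artifacts.

All fixtures are generated programmatically and seeded, so the suite is
deterministic and ships no data files.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nichecore import OtuTable, SampleMetadata
from nichecore import synthetic_data as sd

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec() -> sd.SyntheticSpec:
    """Three species, 300 OTUs each — the default design scaled down."""
    return sd.default_spec(
        seed=7, n_otus=300, n_core=30, samples_per_niche=(12, 6, 10), library_size=5000
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    return sd.generate_community(small_spec)


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return sd.generate_gene_reference(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_table(rng, n_samples=8, n_otus=20, max_count=50) -> OtuTable:
    counts = rng.integers(0, max_count + 1, size=(n_samples, n_otus))
    counts[:, 0] += 1  # guard against zero library sizes
    return OtuTable.from_arrays(
        counts,
        [f"S{i}" for i in range(n_samples)],
        [f"OTU{j}" for j in range(n_otus)],
    )


def two_group_metadata(sample_ids, group_of, depth=None) -> SampleMetadata:
    frame = pd.DataFrame(
        {
            "Species": "Coral_sp",
            "Niche": [group_of(s) for s in sample_ids],
            "Depth": depth if depth is not None else 10.0,
        },
        index=list(sample_ids),
    )
    return SampleMetadata(frame)
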