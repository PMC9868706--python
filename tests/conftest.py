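import numpy as np
import pandas as pd
import pytest

from chemotyper import FeatureTable, SyntheticConfig, TraitTable, generate_dataset


def small_config(**overrides) -> SyntheticConfig:
    """A fast four-chemotype design used across the unit tests."""
    base = dict(n_collections=40, chemotype_sizes=(12, 10, 10, 8),
                n_replicates=3, n_features=120, markers_per_chemotype=10,
                n_modules=0, trait_links=(), seed=7)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """(FeatureTable, TraitTable, GroundTruth) for the small design."""
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def clean_dataset():
    """Small design without drift or missingness (already analyzable)."""
    return generate_dataset(small_config(drift_amplitude=0.0,
                                         missing_rate=0.0, seed=8))


@pytest.fixture()
def tiny_table():
    """Hand-built 4-sample x 3-feature table with one missing cell."""
    intensities = pd.DataFrame(
        [[10.0, 200.0, 5.0],
         [12.0, np.nan, 6.0],
         [11.0, 210.0, 5.5],
         [11.0, 205.0, 5.5]],
        index=["S1", "S2", "S3", "Q1"], columns=["F1", "F2", "F3"])
    meta = pd.DataFrame({
        "role": ["biological", "biological", "biological", "qc"],
        "injection_order": [2, 3, 4, 1],
        "collection_id": ["C1", "C1", "C2", "QC"],
        "replicate_id": ["R1", "R2", "R1", "QC1"],
        "platform": "lcms_pos",
    }, index=intensities.index)
    return FeatureTable(intensities, meta)
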