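"""Shared fixtures: one moderate synthetic study, preprocessed once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plantmet import feature_table as ft
from plantmet import spatial
from plantmet.cln import prepare_design
from plantmet.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced feature panel, full sampling design, all effect types planted."""
    return SimulationConfig(
        seed=42, n_features=80, n_rsd_violators=20,
        n_region_features=9, n_ph_features=6, n_habitat_features=3,
        n_leafarea_features=3,
    )


@pytest.fixture(scope="session")
def study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def preprocessed(study):
    """(averaged_table, leaf_meta, truth) after normalize -> filter -> average."""
    table, meta, truth = study
    norm = ft.normalize_total_intensity(table)
    qc_ids = meta.index[meta["role"] == ft.ROLE_QC]
    filtered, _ = ft.qc_rsd_filter(norm, qc_ids)
    averaged, leaf_meta = ft.average_replicates(filtered, meta)
    return averaged, leaf_meta, truth


@pytest.fixture(scope="session")
def design(preprocessed):
    _, leaf_meta, _ = preprocessed
    pops = leaf_meta.groupby("population")[["latitude", "longitude"]].first()
    axes = spatial.pcnm(spatial.euclidean_distance(pops))
    return prepare_design(leaf_meta, axes.to_frame())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_table() -> ft.FeatureTable:
    """Three samples x three features with easy hand-checkable numbers."""
    df = pd.DataFrame(
        [[2.0, 3.0, 5.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["2.41_343.82", "1.5_200.1", "3.0_500.5"],
    )
    return ft.FeatureTable(df)
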