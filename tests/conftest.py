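"""Shared fixtures: tiny hand-built datasets and small generated cohorts."""

import numpy as np
import pandas as pd
import pytest

from sweatvoc import Dataset, DescriptorLibrary, GeneratorConfig, generate_cohort


@pytest.fixture
def tiny_library() -> DescriptorLibrary:
    return DescriptorLibrary(
        ids=("A", "B", "C"), names=("alpha", "beta", "gamma")
    )


def build_dataset(library, rows, areas, transform_state="raw") -> Dataset:
    """rows: list of (subject, site, status, batch, replicate)."""
    meta = pd.DataFrame(
        rows, columns=["subject_id", "site", "status", "batch", "replicate"]
    )
    return Dataset(library, meta, np.asarray(areas, dtype=float), transform_state)


@pytest.fixture
def tiny_dataset(tiny_library) -> Dataset:
    rows = [
        ("s1", "breast", "pre", "column2", 1),
        ("s1", "breast", "pre", "column2", 2),
        ("s1", "breast", "post", "column2", 1),
        ("s2", "breast", "pre", "column2", 1),
        ("s2", "breast", "post", "column2", 1),
        ("s2", "breast", "post", "column2", 2),
    ]
    areas = [
        [0.0, 5.5, 120.0],
        [0.0, 6.0, 110.0],
        [3.0, 0.0, 10.0],
        [0.5, 7.0, 130.0],
        [2.5, 0.0, 12.0],
        [2.0, 0.1, 11.0],
    ]
    return build_dataset(tiny_library, rows, areas)


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """Strong-signal cohort small enough for fast model tests."""
    return generate_cohort(
        GeneratorConfig(
            n_subjects=10,
            n_post_subjects=7,
            n_descriptors=120,
            replicates_per_sampling=2,
            nonzero_range=(30, 70),
            n_planted=12,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def null_cohort() -> Dataset:
    """No planted effect: downstream stages should find no structure."""
    return generate_cohort(
        GeneratorConfig(
            n_subjects=10,
            n_post_subjects=10,
            n_descriptors=120,
            replicates_per_sampling=2,
            nonzero_range=(30, 70),
            effect_size=0.0,
            dropout_shift=0.0,
            seed=12,
        )
    )
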