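"""Shared fixtures: a micro synthetic dataset and desk-scale configs.

The micro dataset (12 series x 6 frames at 16 px) exists to exercise code
paths quickly; statistical claims are tested elsewhere at the benchmark's
own scale.
"""

import numpy as np
import pytest

from phenodistill.data import (SeriesCache, SplitSpec, assemble_series,
                               read_manifest, split_series)
from phenodistill.synthetic import SynthConfig, generate_dataset

MICRO_SYNTH = dict(n_series=12, frames_per_series=6, image_size=16, seed=7)


@pytest.fixture(scope="session")
def micro_config() -> SynthConfig:
    return SynthConfig(**MICRO_SYNTH)


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory, micro_config):
    """(root dir, manifest DataFrame) of a small generated dataset."""
    root = tmp_path_factory.mktemp("micro_dataset")
    manifest = generate_dataset(micro_config, root)
    return root, manifest


@pytest.fixture(scope="session")
def micro_samples(micro_dataset, micro_config):
    root, _ = micro_dataset
    records = read_manifest(root / "manifest.csv")
    return assemble_series(records, L=micro_config.frames_per_series)


@pytest.fixture(scope="session")
def micro_splits(micro_samples):
    return split_series(micro_samples, SplitSpec(seed=0))


@pytest.fixture(scope="session")
def micro_cache(micro_dataset):
    root, _ = micro_dataset
    return SeriesCache(root)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
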