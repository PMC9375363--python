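import numpy as np
import pandas as pd
import pytest

from nir2dcos import (GeneratorConfig, generate_dataset, generate_manifest,
                      uniform_counts)


@pytest.fixture(scope="session")
def small_manifest() -> pd.DataFrame:
    """2 regions x 4 drying methods x 5 samples = 40 samples."""
    return generate_manifest(uniform_counts(("Guizhou", "Shaanxi"), 5))


@pytest.fixture(scope="session")
def small_dataset(small_manifest):
    """Clean, strongly separated spectra for the small manifest."""
    config = GeneratorConfig(seed=11).strong()
    return generate_dataset(config, small_manifest), small_manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
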