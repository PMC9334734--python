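import numpy as np
import pytest

from immunome.phylo import RateModel
from immunome.rules import default_catalog
from immunome.simulate import SimConfig, generate_annotation_bundle


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def model():
    return RateModel()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, catalog):
    """One default synthetic bundle shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_annotation_bundle(SimConfig(seed=7), outdir, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
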