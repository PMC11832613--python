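import numpy as np
import pytest

from ichscreen.config import PipelineConfig
from ichscreen.phantom import PhantomSpec, generate_phantom, make_fixture_suite


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory):
    """The standard phantom fixture suite (seed 7), generated once per session."""
    d = tmp_path_factory.mktemp("suite")
    make_fixture_suite(d, seed=7)
    return d


@pytest.fixture(scope="session")
def clean_phantom():
    """A lesion-free default phantom volume with its ground truth."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
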