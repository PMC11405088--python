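import numpy as np
import pytest

from binderclust import ScreenSpec, generate_screen, load_screen


@pytest.fixture(scope="session")
def small_spec() -> ScreenSpec:
    """A small screen: 3 families x 4 members + 5 decoys."""
    return ScreenSpec(
        n_families=3, members_per_family=4, n_decoys=5, seed=7
    )


@pytest.fixture(scope="session")
def small_screen_dir(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_screen")
    generate_screen(small_spec, out)
    return out


@pytest.fixture(scope="session")
def small_records(small_screen_dir):
    return load_screen(small_screen_dir)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
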