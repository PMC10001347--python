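import numpy as np
import pytest

from dermforge.fixtures import build_corpus


@pytest.fixture(scope="session")
def corpus32(tmp_path_factory):
    """Small 32px corpus: 8 per class, half fake, deterministic."""
    out = tmp_path_factory.mktemp("corpus32")
    return build_corpus(n_per_class=8, fake_fraction=0.5, out_dir=out,
                        seed=3, size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
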