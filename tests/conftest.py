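import numpy as np
import pytest

from mgecompare.seq_io import CircularSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_circle(rng):
    def make(length=600, seed=None, circular=True):
        r = np.random.default_rng(seed) if seed is not None else rng
        return CircularSequence(
            f"rand{seed}", "".join(r.choice(list("ACGT"), size=length)), circular)
    return make


@pytest.fixture(scope="session")
def small_synth_set():
    """One 4-replicon synthetic set shared across tests (generation is the
    expensive step)."""
    from mgecompare.synthetic import SynthConfig, generate_set
    cfg = SynthConfig(n_replicons=4, subfamily_split=(2, 2), seed=42)
    return generate_set(cfg)
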