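import numpy as np
import pytest

from zfbind import mutscan as mz
from zfbind import synthetic as syn
from zfbind.motifstats import SiteSequence


@pytest.fixture(scope="session")
def config():
    return syn.WorldConfig(seed=7)


@pytest.fixture(scope="session")
def world(config):
    return syn.make_world(config)


@pytest.fixture(scope="session")
def hotspot(world):
    return world.hotspots[0]


@pytest.fixture(scope="session")
def clean_profile(hotspot, config):
    """Noise-free specificity profile of the planted site."""
    quiet = syn.WorldConfig(seed=config.seed, noise_sigma=0.0)
    rng = np.random.default_rng(0)
    measurements = syn.simulate_mutscan(hotspot, quiet, rng)
    return mz.profile_summary(measurements)


def make_sequence(rng, length):
    return SiteSequence("random", "".join(rng.choice(list("ACGT"), size=length)))
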