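import numpy as np
import pytest

from sphingolink import SimConfig, Spectrum, Peak, generate_community, generate_lipids


def make_spectrum(feature_id, precursor_mz, peaks):
    """Spectrum from a list of (mz, intensity) pairs."""
    return Spectrum(feature_id=feature_id, precursor_mz=precursor_mz,
                    peaks=[Peak(m, i) for m, i in peaks])


@pytest.fixture(scope="session")
def small_config():
    # compact community: fast enough for per-test regeneration at session scope
    return SimConfig(seed=11, n_mags=30, n_producer_mags=4, n_lipids=21,
                     scaffolds_per_mag=(12, 15))


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def small_lipids(small_config, small_community):
    comm = small_community
    return generate_lipids(small_config, comm.truth, comm.mags)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
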