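import numpy as np
import pytest

import rootzones as rz


def random_small_profile(rng, T=None):
    """A short random profile for brute-force comparisons."""
    if T is None:
        T = int(rng.integers(8, 13))
    positions = np.sort(rng.uniform(0, 100, T))
    lengths = rng.uniform(1, 30, T)
    return rz.CellLengthProfile("small", positions, lengths)


def merged_mz_spec(n_files=1):
    """Three zones with a short, sparse, high-dispersion mature zone, making
    the elongation and mature zones prone to merging at the selected J."""
    zones = (
        rz.ZoneSpec("DZ", 500.0, 6.0, 0.0, 1.5),
        rz.ZoneSpec("EZ", 400.0, 6.0 - 80 / 1000 * 500, 80.0, 6.0),
        rz.ZoneSpec("MZ", 950.0, 38.0 - 5 / 1000 * 900, 5.0, 25.0),
    )
    return rz.ProfileSpec("merged", zones, n_files=n_files)


@pytest.fixture(scope="session")
def tables():
    return rz.load_table_fixtures()


@pytest.fixture(scope="session")
def a10_profile():
    profile, truth = rz.generate_profile(rz.a10_like_spec(), seed=3)
    return profile, truth


@pytest.fixture(scope="session")
def a10_fit(a10_profile):
    profile, truth = a10_profile
    return rz.PiecewiseLinearModel(profile).fit(3)
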