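import numpy as np
import pytest

import elastofun as ef


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_acq():
    """Desk-scale slab: same physics, smaller matrix."""
    return ef.AcquisitionSpec(matrix_xy=20, n_slices=6)


@pytest.fixture
def short_paradigm():
    """Two 24 s blocks (48 s, 4 elastogram bins)."""
    return ef.ParadigmSpec(n_blocks=2, block_s=24.0)


@pytest.fixture
def quiet_phantom():
    """Noiseless phantom with no embedded effects."""
    return ef.PhantomSpec(
        seed=7, noise_sd=0.0, delta_mu_frac_at_100=0.0, bold_frac_at_100=0.0
    )
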