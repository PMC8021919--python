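import numpy as np
import pytest

from brainage.synthetic import PhantomConfig, make_atlas, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy phantom cohort shared by read-only tests."""
    cfg = PhantomConfig(
        n_subjects=40, grid=(12, 12, 12), n_parcels=10, noise_sd=0.05, seed=123
    )
    atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
    volumes, table = make_cohort(cfg, atlas=atlas)
    return cfg, atlas, volumes, table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
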