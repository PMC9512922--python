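import numpy as np
import pytest

from dormaflux import stats, synthetic


@pytest.fixture(scope="session")
def default_session():
    """One default-noise generated session with its ground truth."""
    profile = synthetic.PHASE_PROFILES[("fast", "TMRE", "regression")]
    return synthetic.generate_imaging_session(
        profile, synthetic.SessionParams(shape=(256, 256)), seed=7
    )


@pytest.fixture
def noiseless_params():
    return synthetic.SessionParams(shape=(64, 64), noise_scale=0.0)


@pytest.fixture
def flat_profile():
    """Degenerate profile: constant signal everywhere."""
    return synthetic.PhaseProfile(
        phase="primary",
        probe="NBDG",
        mean_signal=2000.0,
        dispersion=0.0,
        coverage_fraction=1.0,
    )


def make_null_pools(rng, n_mice=5, n_px=120, icc_sd=0.4, pixel_sd=0.2, shift=0.0):
    """Two pixel pools sharing a distribution, with a strong mouse-level
    random effect (log-normal intercept per mouse)."""
    pools = []
    for g, delta in (("A", 0.0), ("B", shift)):
        vals, ids = [], []
        for m in range(n_mice):
            level = np.exp(delta + icc_sd * rng.standard_normal())
            v = level * np.exp(pixel_sd * rng.standard_normal(n_px))
            vals.append(v)
            ids.append(np.full(n_px, f"{g}{m}", dtype=object))
        pools.append(
            stats.PixelPool(np.concatenate(vals), np.concatenate(ids), group=g)
        )
    return pools
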