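import numpy as np
import pytest

from neurosync.ratings import hrf_convolve, resample_to_tr
from neurosync.synth import (
    RegionSpec,
    SimulationConfig,
    generate_ensemble,
    generate_rating_trace,
)
from neurosync.types import RatingTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def smooth_trace():
    """A slow bounded rating trace at the stimulus sampling rate."""
    return generate_rating_trace(duration_s=1176.0, dt=4.0, seed=7)


def make_trace(values, dt=4.0, rater_id="r"):
    values = np.asarray(values, dtype=float)
    return RatingTrace(np.arange(len(values)) * dt, values, rater_id)


def make_regressor(n_volumes=120, tr=2.6, seed=5):
    trace = generate_rating_trace(duration_s=n_volumes * tr, dt=4.0, seed=seed)
    return hrf_convolve(resample_to_tr(trace, tr, n_volumes))


def small_config(seed=3, **overrides):
    """A compact two-region configuration for fast end-to-end tests."""
    defaults = dict(
        n_subjects=6,
        grid=(10, 10, 6),
        n_volumes=120,
        tr=2.6,
        region_specs=(
            RegionSpec("amp", "AMP+SYNC-", (1, 5, 1, 5, 1, 5)),
            RegionSpec("sync", "AMP-SYNC+", (5, 9, 5, 9, 1, 5)),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def small_ensemble(seed=3, **overrides):
    cfg = small_config(seed=seed, **overrides)
    reg = make_regressor(cfg.n_volumes, cfg.tr, seed=seed)
    ensemble, truth = generate_ensemble(cfg, reg)
    return ensemble, truth, reg, cfg
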