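import numpy as np
import pytest

from petpaint.image import SUVImage
from petpaint.preprocessing import GreyLevelVolume


def make_image(values, spacing=(1.0, 1.0, 1.0)):
    """SUVImage from an array, grid centred on the origin."""
    values = np.asarray(values, dtype=float)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(values.shape, spacing))
    return SUVImage(values=values, spacing=spacing, origin=origin)


def make_glv(levels, mask=None, n_levels=None):
    """GreyLevelVolume from an integer level array (0 = outside VOI)."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    if n_levels is None:
        n_levels = int(levels.max())
    return GreyLevelVolume(levels=levels, mask=np.asarray(mask, dtype=bool),
                           n_levels=n_levels, method="FBS", bin_width=1.0)


def random_glv(rng, max_shape=5, max_levels=6):
    """Random small grey-level volume with a random (non-empty) VOI."""
    shape = tuple(rng.integers(2, max_shape + 1, size=3))
    levels = rng.integers(1, max_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    levels = np.where(mask, levels, 0)
    return make_glv(levels, mask, n_levels=max_levels)


@pytest.fixture(scope="session")
def default_run():
    """One full default experiment (3 lesions × 8 settings × 2 discretizations).

    Session-scoped: the same run backs the design-count and the qualitative
    ordering checks.
    """
    from petpaint.pipeline import ExperimentConfig, run_experiment

    table, report = run_experiment(ExperimentConfig(seed=0))
    return table, report
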