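import numpy as np
import pytest

from fetmri.grids import LesionMask, VoxelGrid
from fetmri.phantoms import PhantomSpec
from fetmri.texture import QuantizedVOI


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def make_random_voi(rng, max_side=6, max_levels=8, G=8):
    """Small random quantized VOI for oracle-equivalence checks."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if mask.sum() < 2:
        mask.flat[:2] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, max_levels + 1, size=int(mask.sum()))
    return QuantizedVOI(levels=levels, mask=mask, G=G, lower=0.0, upper=1.0, degenerate=False)


@pytest.fixture
def random_voi_factory(rng):
    def factory():
        return make_random_voi(rng)

    return factory


def equal_class_params():
    """class_params with no between-class differences (null cohorts)."""
    return {"recurrence": {}, "injury": {}}


def clean_spec(**overrides):
    """Deterministic phantom spec: no per-case jitter, no class contrast unless asked."""
    defaults = dict(
        grid_shape=(32, 32, 32),
        lesion_radius_mm=6.0,
        lesion_radius_sd_mm=0.0,
        shape_irregularity_sd=0.0,
        texture_amp_sd=0.0,
        tbr_sd=0.0,
        class_params=equal_class_params(),
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def small_spec():
    """Small default-contrast cohort spec used by pipeline-level tests."""
    return PhantomSpec(grid_shape=(32, 32, 32), lesion_radius_mm=5.5,
                       lesion_radius_sd_mm=0.8, seed=11)


def constant_grid(value=1.0, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), modality="T1CE"):
    return VoxelGrid(np.full(shape, float(value)), spacing, modality=modality)


def ball_mask(shape=(24, 24, 24), radius_mm=8.0, spacing=(1.0, 1.0, 1.0)):
    axes = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    return LesionMask(dist <= radius_mm, spacing)
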