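import numpy as np
import pytest

from petmtv import SuvVolume, VoiMask


def make_volume(values, spacing=(10.0, 10.0, 10.0)) -> SuvVolume:
    return SuvVolume(np.asarray(values, dtype=np.float32), spacing)


def cube_volume(
    shape=(12, 12, 12), lo=(4, 4, 4), hi=(7, 7, 7), suv=5.0, background=1.0,
    spacing=(10.0, 10.0, 10.0),
) -> SuvVolume:
    """Uniform cuboid lesion on a uniform background; 10 mm voxels = 1 ml."""
    vals = np.full(shape, background, dtype=np.float32)
    vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = suv
    return SuvVolume(vals, spacing)


def digitized_sphere(radius_mm=20.0, suv=10.0, background=0.0, spacing=(2.0, 2.0, 2.0),
                     shape=(40, 40, 40)):
    """Sphere painted by voxel-center membership; returns (volume, true mask)."""
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    center = [(n - 1) * d / 2 for n, d in zip(shape, spacing)]
    inside = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2 \
        <= radius_mm ** 2
    vals = np.where(inside, suv, background).astype(np.float32)
    return SuvVolume(vals, spacing), inside


def random_mask(volume: SuvVolume, rng, p=0.2) -> VoiMask:
    return VoiMask.from_volume(volume, rng.uniform(size=volume.shape) < p)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
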