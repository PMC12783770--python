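import numpy as np
import pytest

from neuritelab.phantom import IntensityModel, default_config, generate_phantom
from neuritelab.volume import LayerAnnotation, VoxelVolume


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise default phantom (3 neurons + distractors), shared."""
    config = default_config(seed=11, intensity=IntensityModel(background_sd=0.0))
    volume, truth = generate_phantom(config)
    return config, volume, truth


@pytest.fixture()
def small_layers():
    return LayerAnnotation(gcl_ipl=10, ipl_inl=20, n_sections=30)


def make_volume(mask: np.ndarray, dark=20, light=200, voxel=(100.0, 100.0, 50.0), layers=None):
    """Binary mask -> 8-bit volume with dark foreground."""
    data = np.where(mask, dark, light).astype(np.uint8)
    if layers is None:
        nz = mask.shape[0]
        layers = LayerAnnotation(gcl_ipl=max(1, nz // 3), ipl_inl=max(2, 2 * nz // 3), n_sections=nz)
    return VoxelVolume(data=data, voxel_size_nm=voxel, layers=layers)


def ball_voxels(center, radius):
    """Integer lattice points within a Euclidean ball (voxel units)."""
    c = np.asarray(center)
    r = int(np.ceil(radius))
    grid = np.stack(
        np.meshgrid(*[np.arange(ci - r, ci + r + 1) for ci in c], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d2 = ((grid - c) ** 2).sum(axis=1)
    return grid[d2 <= radius**2]
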