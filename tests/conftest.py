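import numpy as np
import pytest

import embryomap as em


@pytest.fixture(scope="session")
def small_embryo_spec() -> em.EmbryoSpec:
    """A fast 64³ embryo with a dense, noiseless cell shell."""
    return em.EmbryoSpec(
        volume_shape=(64, 64, 64),
        voxel_spacing=(1.5, 1.0, 1.0),
        sphere_radius=18.0,
        n_cells=120,
        cell_sigma=1.5,
        cell_amplitude=100.0,
        background=5.0,
        min_cell_separation=3.0,
        noise=em.NoiseModel("none"),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_embryo(small_embryo_spec):
    return em.generate_volume(small_embryo_spec)


def render_blobs(shape, spacing, positions, sigma, amplitude):
    """Reference blob renderer used as an independent construction in tests."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    data = np.zeros(shape)
    for p in np.atleast_2d(positions):
        d2 = sum((g - c) ** 2 for g, c in zip(grids, p))
        data += amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return data
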