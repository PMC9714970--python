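import numpy as np
import pytest

from bundlequant import PhantomSpec, ProbeModel, simulate_stack


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free two-cell phantom with an 8x-enriched probe."""
    spec = PhantomSpec(
        n_cells=2,
        probes=(
            ProbeModel("PM", stereocilia_enrichment=1.0),
            ProbeModel("D4H", stereocilia_enrichment=8.0),
        ),
        shot_noise=False,
        read_noise_sd=0.0,
        psf_sigma_um=0.0,
        seed=11,
    )
    stack, truth = simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry under the default noise model."""
    spec = PhantomSpec(
        n_cells=2,
        probes=(
            ProbeModel("PM", stereocilia_enrichment=1.0),
            ProbeModel("D4H", stereocilia_enrichment=8.0),
        ),
        seed=11,
    )
    stack, truth = simulate_stack(spec)
    return spec, stack, truth


def voxelized_sphere(diameter_um, voxel_um, pad_um=0.5):
    """Boolean sphere mask by centre-of-voxel inclusion (test oracle geometry)."""
    extent = diameter_um + 2 * pad_um
    n = int(np.ceil(extent / voxel_um))
    c = n * voxel_um / 2.0
    coords = (np.arange(n) + 0.5) * voxel_um
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= (diameter_um / 2.0) ** 2
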