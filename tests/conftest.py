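import numpy as np
import pytest

from stromaprox import PhantomSpec, compute_enhancement_maps, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom without noise, with its ground truth."""
    series, truth = generate_phantom(PhantomSpec(noise_sigma=0.0, seed=0))
    return series, truth


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    series, _ = noiseless_phantom
    return compute_enhancement_maps(series)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, fast phantom for pipeline-level tests."""
    spec = PhantomSpec(
        shape=(40, 40, 24),
        spacing=(2.5, 2.5, 3.0),
        tumor_radii_mm=(8.0, 8.0, 8.0),
        shell_extent_mm=42.0,
        noise_sigma=0.0,
        seed=7,
    )
    return generate_phantom(spec)


def brute_force_distance(tumor_mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive nearest-tumor-voxel distance; the oracle for the EDT."""
    spacing = np.asarray(spacing, dtype=float)
    tumor_idx = np.argwhere(tumor_mask) * spacing
    out = np.zeros(tumor_mask.shape)
    for idx in np.ndindex(tumor_mask.shape):
        if tumor_mask[idx]:
            continue
        p = np.asarray(idx) * spacing
        out[idx] = np.sqrt(((tumor_idx - p) ** 2).sum(axis=1)).min()
    return out
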