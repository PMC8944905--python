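import numpy as np
import pytest

from fbrquant.types import PhantomSpec


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless phantom with known geometry, shared across tests."""
    from fbrquant.synthetic import generate_nerve_phantom

    spec = PhantomSpec(
        image_size_px=(256, 256),
        pixel_size_um=1.0,
        nerve_radius_um=100.0,
        capsule_thickness_um=40.0,
        intensity_decay_um=15.0,
        axon_density_per_mm2=800.0,
        nuclei_density_per_mm2=1000.0,
        noise_sd=0.0,
        seed=42,
    )
    return spec, generate_nerve_phantom(spec)


def star_polygon(rng: np.random.Generator, n_vertices: int, center, r_min, r_max) -> np.ndarray:
    """Random star-shaped (hence simple) polygon vertices, (n, 2) of (x, y)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(r_min, r_max, size=n_vertices)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )
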