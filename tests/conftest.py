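import numpy as np
import pytest

import spirestore as sp
from spirestore.datasets import DatasetSpec, build_dataset


@pytest.fixture(scope="session")
def small_geometry():
    """64-pixel detector with the study's effective 800 um pixel."""
    return sp.DetectorGeometry(8.0, 0.15, 800e-6, 64)


@pytest.fixture(scope="session")
def desk_dataset():
    """Shared 60-pattern blob dataset at f=10, 64x64 output."""
    geo = sp.DetectorGeometry(8.0, 0.15, 400e-6, 128)
    spec = DatasetSpec(
        n_patterns=60, intensity_factors=(10.0,), geometry=geo, bin_factor=2, seed=11
    )
    return build_dataset(spec)


@pytest.fixture(scope="session")
def lattice_pattern(small_geometry):
    """Pattern from a particle whose points sit on the detector-conjugate
    real-space lattice: its intensity is an on-grid trigonometric
    polynomial, so the discrete autocorrelation is exactly compactly
    supported (no spectral leakage)."""
    from spirestore.particles import Particle
    from spirestore.simulate import simulate_pattern

    g = small_geometry
    dx = g.wavelength * g.distance / (g.n_side * g.pixel_size)
    rng = np.random.default_rng(9)
    pts = rng.integers(-6, 7, size=(40, 3)) * dx
    w = rng.random(40) + 0.5
    particle = Particle("atoms", pts, w)
    return simulate_pattern(particle, g, flat_ewald=True)


@pytest.fixture(scope="session")
def sphere_pattern(small_geometry):
    particle = sp.shape_particle("sphere", 4e-9)
    return sp.simulate_pattern(particle, small_geometry)


@pytest.fixture(scope="session")
def blob_pattern(small_geometry):
    particle = sp.blob_particle(50.0, seed=1)
    return sp.simulate_pattern_fft(particle, small_geometry)
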