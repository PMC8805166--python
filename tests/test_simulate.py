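import numpy as np
import pytest

import spirestore as sp
from spirestore.geometry import DetectorGeometry, Orientation, detector_qmap
from spirestore.particles import Particle
from spirestore.simulate import (
    DiffractionPattern,
    NoiseConfig,
    downsample,
    normalize_max,
    poisson_corrupt,
    simulate_pattern,
    simulate_pattern_fft,
    sphere_amplitude,
)


def interior_friedel_asymmetry(values: np.ndarray) -> float:
    """Max |I(q) - I(-q)| / max I over pixels whose partner is on the grid."""
    J = values[1:, 1:]
    return float(np.abs(J - np.flip(J)).max() / values.max())


class TestSimulatePattern:
    def test_single_point_gives_flat_intensity(self, small_geometry):
        p = Particle("atoms", [[0.0, 0.0, 0.0]], [2.0])
        pat = simulate_pattern(p, small_geometry)
        assert np.allclose(pat.values, 4.0, rtol=1e-12)

    def test_two_point_fringe_period(self, small_geometry):
        """Two scatterers separated by d give cosine fringes of period
        lambda*L/(d*p) pixels along the separation axis."""
        g = small_geometry
        period = 8  # pixels; choose d so the fringe period is exact
        d = g.wavelength * g.distance / (period * g.pixel_size)
        p = Particle("atoms", [[0, -d / 2, 0], [0, d / 2, 0]], [1.0, 1.0])
        pat = simulate_pattern(p, g, flat_ewald=True)
        c = g.n_side // 2
        row = pat.values[c]  # fringes vary along columns (axis 1)
        assert row[c] == pytest.approx(4.0, rel=1e-9)
        assert row[c + period] == pytest.approx(4.0, rel=1e-9)
        assert row[c + period // 2] == pytest.approx(0.0, abs=1e-9)

    def test_sphere_matches_closed_form(self, small_geometry, sphere_pattern):
        """Uniform-sphere intensities follow [3(sin u - u cos u)/u^3]^2 with
        u = qR; first zero at u ~ 4.493."""
        qmag = np.linalg.norm(detector_qmap(small_geometry), axis=-1)
        R = 2e-9
        u = qmag * R
        safe = np.where(u < 1e-2, 1.0, u)
        form = np.where(
            u < 1e-2,
            (1.0 - u * u / 10.0) ** 2,  # series near the origin
            (3 * (np.sin(safe) - safe * np.cos(safe)) / safe**3) ** 2,
        )
        w = sphere_pattern.values.max() / form.max()
        assert np.abs(sphere_pattern.values - w * form).max() / sphere_pattern.values.max() < 1e-6

    def test_sphere_first_zero_location(self, small_geometry, sphere_pattern):
        c = small_geometry.n_side // 2
        col = sphere_pattern.values[:, c]
        # walk down from the centre to the first minimum
        i = c
        while col[i + 1] < col[i]:
            i += 1
        u_zero = 4.4934
        q_zero = u_zero / 2e-9
        dq = 2 * np.pi * small_geometry.pixel_size / (
            small_geometry.wavelength * small_geometry.distance
        )
        assert abs((i - c) - q_zero / dq) <= 1.0

    def test_friedel_symmetry_flat_ewald(self, small_geometry):
        blob = sp.blob_particle(40.0, seed=2)
        pat = simulate_pattern(blob, small_geometry, flat_ewald=True)
        assert interior_friedel_asymmetry(pat.values) < 1e-9

    def test_friedel_violation_small_with_curvature(self, small_geometry):
        """The exact Ewald map breaks detector-grid Friedel symmetry only at
        the per-mil level at this geometry."""
        blob = sp.blob_particle(40.0, seed=2)
        pat = simulate_pattern(blob, small_geometry)
        assert 0 < interior_friedel_asymmetry(pat.values) < 1e-2

    def test_degenerate_particle_raises(self, small_geometry):
        p = Particle("atoms", [[0.0, 0.0, 0.0]], [0.0])
        with pytest.raises(ValueError):
            simulate_pattern(p, small_geometry)

    def test_fft_engine_matches_direct_flat_ewald(self, small_geometry):
        blob = sp.blob_particle(50.0, seed=1)
        o = Orientation.random(np.random.default_rng(5))
        direct = simulate_pattern(blob, small_geometry, o, flat_ewald=True)
        fast = simulate_pattern_fft(blob, small_geometry, o)
        rel = np.abs(direct.values - fast.values).max() / direct.values.max()
        assert rel < 1e-3


class TestNormalizeMax:
    def test_scales_to_unit_max(self, blob_pattern):
        out = normalize_max(blob_pattern)
        assert out.values.max() == pytest.approx(1.0)
        assert np.argmax(out.values) == np.argmax(blob_pattern.values)

    def test_idempotent(self, blob_pattern):
        once = normalize_max(blob_pattern)
        twice = normalize_max(once)
        assert np.array_equal(once.values, twice.values)

    def test_all_zero_raises(self, small_geometry):
        pat = DiffractionPattern(
            np.zeros((64, 64)), "noiseless", small_geometry
        )
        with pytest.raises(ValueError):
            normalize_max(pat)


class TestDownsample:
    def test_sum_binning_conserves_intensity(self, small_geometry):
        blob = sp.blob_particle(30.0, seed=3)
        pat = simulate_pattern_fft(blob, small_geometry)
        out = downsample(pat, 32)
        assert out.values.sum() == pytest.approx(pat.values.sum(), rel=1e-9)

    def test_uniform_ones_bin_to_fours(self, small_geometry):
        pat = DiffractionPattern(np.ones((64, 64)), "noiseless", small_geometry)
        out = downsample(pat, 32)
        assert np.allclose(out.values, 4.0)

    def test_checkerboard_bins_to_constant_two(self, small_geometry):
        board = np.indices((64, 64)).sum(axis=0) % 2
        pat = DiffractionPattern(board.astype(float), "noiseless", small_geometry)
        assert np.allclose(downsample(pat, 32).values, 2.0)

    def test_factor_one_is_identity(self, blob_pattern):
        out = downsample(blob_pattern, blob_pattern.geometry.n_side)
        assert np.array_equal(out.values, blob_pattern.values)

    def test_upsampling_rejected(self, blob_pattern):
        with pytest.raises(ValueError):
            downsample(blob_pattern, 256)


class TestPoissonCorrupt:
    def test_zero_pattern_gives_zero_counts(self, small_geometry):
        pat = DiffractionPattern(np.zeros((64, 64)), "noiseless", small_geometry)
        out = poisson_corrupt(pat, NoiseConfig(10.0, seed=0))
        assert out.values.sum() == 0

    def test_deterministic_under_seed(self, blob_pattern):
        pat = normalize_max(blob_pattern)
        a = poisson_corrupt(pat, NoiseConfig(10.0, seed=4), pattern_index=7)
        b = poisson_corrupt(pat, NoiseConfig(10.0, seed=4), pattern_index=7)
        c = poisson_corrupt(pat, NoiseConfig(10.0, seed=4), pattern_index=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_counts_are_integers(self, blob_pattern):
        out = poisson_corrupt(normalize_max(blob_pattern), NoiseConfig(100.0, seed=1))
        assert np.array_equal(out.values, np.rint(out.values))

    def test_linearized_mse_follows_poisson_variance(self, blob_pattern):
        """E[(K/f - I)^2] averaged over pixels equals mean(I)/f."""
        pat = normalize_max(blob_pattern)
        f = 10.0
        draws = [
            poisson_corrupt(pat, NoiseConfig(f, seed=2), pattern_index=k).values / f
            for k in range(200)
        ]
        mse = np.mean([(d - pat.values) ** 2 for d in draws])
        assert mse == pytest.approx(pat.values.mean() / f, rel=0.05)

    def test_large_factor_recovers_pattern(self, blob_pattern):
        pat = normalize_max(blob_pattern)
        f = 1e6
        k = poisson_corrupt(pat, NoiseConfig(f, seed=3)).values / f
        strong = pat.values > 0.01
        rel_rms = np.sqrt(np.mean(((k - pat.values)[strong] / pat.values[strong]) ** 2))
        assert rel_rms < 0.01

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(0.0)
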