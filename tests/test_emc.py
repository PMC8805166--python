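import numpy as np
import pytest

import spirestore as sp
from spirestore.emc import (
    EMCConfig,
    FourierModel,
    ResponsibilityMatrix,
    RotationSet,
    blur_model,
    detector_voxel_coords,
    expand,
    maximize_compress,
    mean_grid_spacing,
    orient_against_model,
    responsibilities,
    rotation_error,
    run_emc,
    sample_rotations,
)
from spirestore.geometry import DetectorGeometry, Orientation


@pytest.fixture(scope="module")
def emc_geometry():
    """Small flat-Ewald-friendly detector: 5-6 speckles across 32 pixels."""
    return DetectorGeometry(8.0, 0.15, 3.2e-3, 32)


@pytest.fixture(scope="module")
def emc_patterns(emc_geometry):
    """160 noiseless patterns of one particle at grid rotations."""
    rots = sample_rotations(2)
    blob = sp.blob_particle(30.0, seed=5)
    rng = np.random.default_rng(42)
    idx = rng.integers(0, len(rots), size=160)
    pats = np.asarray(
        [
            sp.simulate_pattern_fft(blob, emc_geometry, Orientation(tuple(q))).values
            for q in rots.quaternions[idx]
        ]
    )
    pats /= pats.max()
    return pats, idx, rots


class TestSampleRotations:
    def test_contains_identity(self):
        rots = sample_rotations(1)
        assert np.allclose(rots.quaternions[0], [1, 0, 0, 0])

    def test_unit_norm_and_weights(self):
        rots = sample_rotations(2)
        assert np.allclose(np.linalg.norm(rots.quaternions, axis=1), 1.0, atol=1e-12)
        assert rots.weights.sum() == pytest.approx(1.0)

    def test_coverage_improves_with_order(self):
        s1 = mean_grid_spacing(sample_rotations(1))
        s2 = mean_grid_spacing(sample_rotations(2))
        s3 = mean_grid_spacing(sample_rotations(3))
        assert s1 > s2 > s3
        assert len(sample_rotations(2)) > len(sample_rotations(1))


class TestExpandCompress:
    def test_single_insert_extract_round_trip(self, emc_geometry):
        """A pattern inserted at one rotation is recovered by slicing the
        resulting model at the same rotation."""
        blob = sp.blob_particle(30.0, seed=5)
        pat = sp.simulate_pattern_fft(blob, emc_geometry).values
        pat = pat / pat.max()
        rots = RotationSet(np.array([[1.0, 0, 0, 0]]), np.array([1.0]))
        model = maximize_compress(
            pat[None], ResponsibilityMatrix(np.array([[1.0]])), rots, emc_geometry, 48
        )
        sl = expand(model, rots, emc_geometry)[0].reshape(32, 32)
        assert np.abs(sl - pat).max() < 1e-9

    def test_expand_matches_direct_evaluation(self, emc_geometry):
        """Slicing an analytically filled model at a rotation agrees with
        simulating the pattern at that orientation (compact few-point
        particle so the only error left is trilinear interpolation)."""
        from spirestore.particles import Particle
        from spirestore.simulate import _direct_sum_numpy

        rng = np.random.default_rng(11)
        particle = Particle(
            "atoms", rng.normal(scale=0.8e-9, size=(12, 3)), rng.random(12) + 0.5
        )
        ns, ss = 144, 3
        qv, dq = detector_voxel_coords(emc_geometry, ns, ss)
        ax = (np.arange(ns) - ns / 2) * dq
        Q = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        F = _direct_sum_numpy(Q, particle.positions, particle.weights, 1 << 16)
        model = FourierModel(
            (np.abs(F) ** 2).reshape(ns, ns, ns), np.ones((ns, ns, ns)), dq
        )
        rots = sample_rotations(1)
        q = rots.quaternions[7]
        pat = sp.simulate_pattern(
            particle, emc_geometry, Orientation(tuple(q)), flat_ewald=True
        ).values
        slices = expand(model, rots, emc_geometry, supersample=ss)
        rel = np.sqrt(np.mean((slices[7].reshape(32, 32) - pat) ** 2)) / np.sqrt(
            np.mean(pat**2)
        )
        assert rel < 0.05  # trilinear interpolation error only

    def test_zero_model_zero_slices(self, emc_geometry):
        model = FourierModel(np.zeros((48,) * 3), np.ones((48,) * 3), 1.0)
        rots = sample_rotations(1)
        assert np.all(expand(model, rots, emc_geometry) == 0)

    def test_spherically_symmetric_model_gives_equal_slices(self, emc_geometry):
        ns = 48
        ax = np.arange(ns) - ns / 2
        r = np.sqrt(((np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1)) ** 2).sum(-1))
        model = FourierModel(np.exp(-r / 5.0), np.ones((ns,) * 3), 1.0)
        slices = expand(model, sample_rotations(1), emc_geometry)
        assert np.abs(slices - slices[0]).max() / slices.max() < 0.05

    def test_duplicate_patterns_same_model_as_single(self, emc_geometry):
        blob = sp.blob_particle(30.0, seed=5)
        pat = sp.simulate_pattern_fft(blob, emc_geometry).values
        rots = RotationSet(np.array([[1.0, 0, 0, 0]]), np.array([1.0]))
        one = maximize_compress(
            pat[None], ResponsibilityMatrix(np.array([[1.0]])), rots, emc_geometry, 48
        )
        two = maximize_compress(
            np.stack([pat, pat]),
            ResponsibilityMatrix(np.array([[1.0], [1.0]])),
            rots,
            emc_geometry,
            48,
        )
        assert np.allclose(one.voxels, two.voxels)

    def test_inserted_weight_conserved(self, emc_geometry):
        """Total insertion weight equals n_patterns x n_pixels."""
        rng = np.random.default_rng(0)
        pats = rng.random((5, 32, 32))
        rots = sample_rotations(1)
        P = rng.dirichlet(np.ones(len(rots)), size=5)
        model = maximize_compress(pats, ResponsibilityMatrix(P), rots, emc_geometry, 64)
        assert model.weights.sum() == pytest.approx(5 * 32 * 32, rel=1e-9)


class TestResponsibilities:
    def test_rows_sum_to_one_both_likelihoods(self, emc_geometry, emc_patterns):
        pats, idx, rots = emc_patterns
        K = pats[:10]
        slices = np.abs(np.random.default_rng(0).normal(size=(20, 1024))) + 0.01
        for like in ("poisson", "gaussian"):
            cfg = EMCConfig(likelihood=like, sigma=0.1)
            resp, _ = responsibilities(np.rint(K * 50), slices, cfg)
            assert np.allclose(resp.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_peak_on_matching_slice(self):
        rng = np.random.default_rng(1)
        slices = rng.random((10, 64)) + 0.1
        pattern = slices[4].reshape(8, 8)
        cfg = EMCConfig(likelihood="gaussian", sigma=0.01)
        resp, _ = responsibilities(pattern[None], slices, cfg)
        assert resp.modes()[0] == 4
        assert resp.probabilities[0, 4] > 0.99

    def test_uniform_slices_give_uniform_responsibilities(self):
        slices = np.ones((12, 64))
        pattern = np.random.default_rng(2).random((8, 8))
        cfg = EMCConfig(likelihood="gaussian", sigma=1.0)
        resp, _ = responsibilities(pattern[None], slices, cfg)
        assert np.allclose(resp.probabilities, 1.0 / 12)

    def test_poisson_matches_brute_force_enumeration(self):
        """Poisson responsibilities equal the directly enumerated
        normalized likelihoods on a tiny instance."""
        rng = np.random.default_rng(3)
        slices = rng.random((6, 16)) * 3 + 0.05
        counts = rng.poisson(2.0, size=(3, 4, 4)).astype(float)
        cfg = EMCConfig(likelihood="poisson")
        resp, _ = responsibilities(counts, slices, cfg)
        from scipy.stats import poisson as poisson_dist

        K = counts.reshape(3, -1)
        brute = np.zeros((3, 6))
        for k in range(3):
            for j in range(6):
                brute[k, j] = np.prod(poisson_dist.pmf(K[k], slices[j]))
        brute /= brute.sum(axis=1, keepdims=True)
        assert np.allclose(resp.probabilities, brute, atol=1e-9)

    def test_masked_pixels_excluded(self, emc_geometry):
        from spirestore.masks import stripe_mask

        rng = np.random.default_rng(4)
        slices = rng.random((5, 1024)) + 0.1
        pattern = slices[2].reshape(32, 32).copy()
        mask = stripe_mask(32, 6)
        pattern[mask.missing] = 999.0  # garbage in masked rows
        cfg = EMCConfig(likelihood="gaussian", sigma=0.01)
        resp, _ = responsibilities(pattern[None], slices, cfg, mask=mask)
        assert resp.modes()[0] == 2


class TestBlurModel:
    def test_zero_sigma_identity(self):
        m = FourierModel(np.random.default_rng(0).random((8, 8, 8)), np.ones((8, 8, 8)), 1.0)
        assert blur_model(m, 0.0) is m

    def test_delta_spreads_and_conserves_mass(self):
        v = np.zeros((16, 16, 16))
        w = np.zeros((16, 16, 16))
        v[8, 8, 8] = 5.0
        w[8, 8, 8] = 2.0
        out = blur_model(FourierModel(v, w, 1.0), 1.0)
        assert (out.voxels * out.weights).sum() == pytest.approx(10.0, rel=1e-6)
        assert out.weights.sum() == pytest.approx(2.0, rel=1e-6)
        assert (out.weights > 1e-6).sum() > 1

    def test_fills_gap_between_nearby_voxels(self):
        w = np.zeros((16, 16, 16))
        w[6, 8, 8] = w[10, 8, 8] = 1.0
        out = blur_model(FourierModel(w.copy(), w, 1.0), 1.5)
        assert out.weights[8, 8, 8] > 1e-3


class TestRunEmc:
    def test_poisson_log_likelihood_monotone_without_blur(self, emc_geometry, emc_patterns):
        """EM monotonicity: with the nearest-voxel kernel the M step is the
        exact maximizer, so the data log-likelihood never decreases."""
        pats, idx, rots = emc_patterns
        counts = np.random.default_rng(7).poisson(100 * pats[:40]).astype(float)
        cfg = EMCConfig(
            likelihood="poisson", iterations=12, model_side=48, supersample=1,
            interp="nearest", seed=0,
        )
        res = run_emc(counts, cfg, emc_geometry, rotations=rots)
        diffs = np.diff(res.log_likelihood)
        assert np.all(diffs >= -1e-7 * np.abs(res.log_likelihood[0]))

    def test_blurred_emc_fills_more_voxels(self, emc_geometry, emc_patterns):
        pats, idx, rots = emc_patterns
        few = pats[:20]
        base = dict(likelihood="gaussian", iterations=6, model_side=96, supersample=2, seed=0)
        plain = run_emc(few, EMCConfig(**base), emc_geometry, rotations=rots)
        blurred = run_emc(
            few, EMCConfig(blur_sigma=1.0, **base), emc_geometry, rotations=rots
        )
        assert blurred.model.n_empty() < plain.model.n_empty()

    def test_too_few_patterns_rejected(self, emc_geometry):
        with pytest.raises(ValueError):
            run_emc(np.zeros((1, 32, 32)), EMCConfig(), emc_geometry)

    def test_footprint_check(self):
        g = DetectorGeometry(8.0, 0.15, 3.2e-3, 128)
        with pytest.raises(ValueError):
            detector_voxel_coords(g, 32)


class TestOrientationScoring:
    def test_zero_error_for_identical_sets(self):
        rots = sample_rotations(1)
        q = rots.quaternions[:20]
        assert rotation_error(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_global_gauge_rotation_removed(self):
        rng = np.random.default_rng(5)
        truth = np.array([Orientation.random(rng).quaternion for _ in range(30)])
        g = np.array(Orientation.random(rng).quaternion)
        from spirestore.emc import _quat_multiply

        rotated = _quat_multiply(g[None, :], truth)
        assert rotation_error(rotated, truth) == pytest.approx(0.0, abs=1e-6)

    def test_random_estimates_match_analytic_mean(self):
        """Without alignment, random rotations sit at the mean angular
        distance of the SO(3) haar measure, pi/2 + 2/pi."""
        rng = np.random.default_rng(6)
        est = np.array([Orientation.random(rng).quaternion for _ in range(400)])
        tru = np.array([Orientation.random(rng).quaternion for _ in range(400)])
        err = rotation_error(est, tru, align=False, friedel=False)
        assert err == pytest.approx(np.pi / 2 + 2 / np.pi, rel=0.05)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            rotation_error(np.zeros((3, 4)), np.zeros((4, 4)))

    def test_heldout_orientation_below_grid_spacing(self, emc_geometry, emc_patterns):
        """Patterns held out of the model orient to better than the grid
        spacing: the orientation-determination half of EMC is accurate."""
        pats, idx, rots = emc_patterns
        n_model = 100
        P = np.zeros((n_model, len(rots)))
        P[np.arange(n_model), idx[:n_model]] = 1.0
        model = maximize_compress(
            pats[:n_model], ResponsibilityMatrix(P), rots, emc_geometry, 144, supersample=3
        )
        cfg = EMCConfig(likelihood="gaussian", supersample=3)
        est = orient_against_model(pats[n_model:], model, rots, emc_geometry, cfg)
        err = rotation_error(est, rots.quaternions[idx[n_model:]])
        assert err < mean_grid_spacing(rots)
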