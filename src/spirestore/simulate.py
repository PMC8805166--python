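"""Forward simulation of far-field diffraction intensities.

Two engines are provided:

* ``simulate_pattern`` -- exact Ewald-sphere direct sum
  I(q) = |sum_j w_j exp(i q . r_j)|^2, correct at any scattering angle.
* ``simulate_pattern_fft`` -- flat-Ewald fast path: the detector plane then
  samples the 3D transform at q_z = 0, which is the 2D transform of the
  beam-axis projection of the density, evaluated with a zero-padded FFT
  after cloud-in-cell deposition.  Orders of magnitude faster; used for
  bulk dataset generation.

Both return centred patterns on the detector grid together with the
complex field (source of the "true phases" oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DetectorGeometry, Orientation, detector_qmap
from .particles import Particle

PATTERN_STATES = ("noiseless", "noisy", "normalized", "restored")


@dataclass
class DiffractionPattern:
    """2D per-pixel intensity with provenance metadata."""

    values: np.ndarray
    state: str
    geometry: DetectorGeometry
    orientation: Orientation | None = None
    mask: np.ndarray | None = None  # boolean, True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in PATTERN_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        n = self.geometry.n_side
        if self.values.shape != (n, n):
            raise ValueError("pattern shape does not match geometry")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")

    def with_values(self, values: np.ndarray, state: str | None = None) -> "DiffractionPattern":
        return replace(self, values=np.asarray(values, dtype=float), state=state or self.state)


@dataclass(frozen=True)
class NoiseConfig:
    """Poisson corruption: counts ~ Poisson(intensity_factor * I)."""

    intensity_factor: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_factor <= 0:
            raise ValueError("intensity_factor must be positive")


def sphere_amplitude(qmag: np.ndarray, diameter: float, total_weight: float) -> np.ndarray:
    """Closed-form scattering amplitude of a uniform sphere.

    F(q) = W * 3 (sin u - u cos u) / u^3 with u = q * D / 2; the first
    intensity zero sits at u ~ 4.493.  A series expansion guards u -> 0.
    """
    u = np.asarray(qmag, dtype=float) * (diameter / 2.0)
    small = np.abs(u) < 1e-4
    us = np.where(small, 1.0, u)
    f = 3.0 * (np.sin(us) - us * np.cos(us)) / us ** 3
    f = np.where(small, 1.0 - u * u / 10.0, f)
    return total_weight * f


def scattered_field(
    particle: Particle,
    geometry: DetectorGeometry,
    orientation: Orientation | None = None,
    flat_ewald: bool = False,
    chunk: int = 8192,
) -> np.ndarray:
    """Complex far-field amplitude F(q) = sum_j w_j exp(i q . r_j).

    The uniform sphere is evaluated with its closed-form amplitude (exact
    physics, orientation-independent); all other particles go through the
    weighted point-cloud direct sum.
    """
    if particle.n_points == 0 or particle.total_weight == 0:
        raise ValueError("degenerate particle: no points or zero total weight")
    q = detector_qmap(geometry, flat_ewald=flat_ewald).reshape(-1, 3)
    if particle.kind == "sphere" and particle.size:
        qmag = np.linalg.norm(q, axis=1)
        F = sphere_amplitude(qmag, particle.size, particle.total_weight)
        return F.astype(complex).reshape(geometry.n_side, geometry.n_side)
    pts = particle.positions
    if orientation is not None:
        pts = pts @ orientation.as_matrix().T
    w = particle.weights
    out = _direct_sum(q, pts, w, chunk)
    return out.reshape(geometry.n_side, geometry.n_side)


def _direct_sum_numpy(q: np.ndarray, pts: np.ndarray, w: np.ndarray, chunk: int) -> np.ndarray:
    out = np.empty(q.shape[0], dtype=complex)
    for start in range(0, q.shape[0], chunk):
        phase = q[start : start + chunk] @ pts.T  # (chunk, N)
        out[start : start + chunk] = np.cos(phase) @ w + 1j * (np.sin(phase) @ w)
    return out


try:  # compiled kernel; trig dominates the direct sum
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _direct_sum_jit(q, pts, w):  # pragma: no cover - exercised via wrapper
        npix = q.shape[0]
        npts = pts.shape[0]
        out = np.empty(npix, dtype=np.complex128)
        for i in range(npix):
            re = 0.0
            im = 0.0
            for j in range(npts):
                ph = q[i, 0] * pts[j, 0] + q[i, 1] * pts[j, 1] + q[i, 2] * pts[j, 2]
                re += w[j] * np.cos(ph)
                im += w[j] * np.sin(ph)
            out[i] = complex(re, im)
        return out

    def _direct_sum(q, pts, w, chunk):
        return _direct_sum_jit(
            np.ascontiguousarray(q), np.ascontiguousarray(pts), np.ascontiguousarray(w)
        )

except ImportError:  # pragma: no cover

    def _direct_sum(q, pts, w, chunk):
        return _direct_sum_numpy(q, pts, w, chunk)


def simulate_pattern(
    particle: Particle,
    geometry: DetectorGeometry,
    orientation: Orientation | None = None,
    flat_ewald: bool = False,
) -> DiffractionPattern:
    """Noiseless diffraction intensities by exact direct summation."""
    F = scattered_field(particle, geometry, orientation, flat_ewald=flat_ewald)
    return DiffractionPattern(np.abs(F) ** 2, "noiseless", geometry, orientation)


def _deposit_cic(xy: np.ndarray, w: np.ndarray, n_grid: int, dx: float) -> np.ndarray:
    """Cloud-in-cell (bilinear) deposition of weighted points on a 2D grid."""
    grid = np.zeros((n_grid, n_grid))
    gx = xy[:, 0] / dx + n_grid / 2.0
    gy = xy[:, 1] / dx + n_grid / 2.0
    if np.any(gx < 0) or np.any(gx >= n_grid - 1) or np.any(gy < 0) or np.any(gy >= n_grid - 1):
        raise ValueError("particle too large for the FFT field of view")
    ix = np.floor(gx).astype(int)
    iy = np.floor(gy).astype(int)
    fx = gx - ix
    fy = gy - iy
    np.add.at(grid, (ix, iy), w * (1 - fx) * (1 - fy))
    np.add.at(grid, (ix + 1, iy), w * fx * (1 - fy))
    np.add.at(grid, (ix, iy + 1), w * (1 - fx) * fy)
    np.add.at(grid, (ix + 1, iy + 1), w * fx * fy)
    return grid


def simulate_field_fft(
    particle: Particle,
    geometry: DetectorGeometry,
    orientation: Orientation | None = None,
    pad_factor: int = 2,
) -> np.ndarray:
    """Flat-Ewald complex field on the detector grid via a padded 2D FFT.

    The q-space sampling interval of the detector, dq = 2*pi*p/(lambda*L),
    fixes the real-space field of view X = 2*pi/dq = lambda*L/p; the grid is
    padded by ``pad_factor`` for sub-pixel deposition accuracy.
    """
    n = geometry.n_side
    n_grid = n * pad_factor
    fov = geometry.wavelength * geometry.distance / geometry.pixel_size
    dx = fov / n_grid
    pts = particle.positions
    if orientation is not None:
        pts = pts @ orientation.as_matrix().T
    # grid axis 0 follows detector rows (q_row pairs with particle axis 0)
    grid = _deposit_cic(pts[:, :2], particle.weights, n_grid, dx)
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(grid)))
    # deconvolve the bilinear (CIC) deposition kernel: its transform is
    # sinc^2 along each axis on the FFT grid
    k = (np.arange(n_grid) - n_grid // 2) / n_grid
    s = np.sinc(k) ** 2
    F = F / (s[:, None] * s[None, :])
    # FFT bin spacing 2*pi/fov equals the detector q-spacing by construction,
    # so the central n x n block IS the detector; padding only refines dx
    c = n_grid // 2
    sel = slice(c - n // 2, c + n // 2)
    return np.conj(F[sel, sel])  # exp(+i q.r) convention as in the direct sum


def simulate_pattern_fft(
    particle: Particle,
    geometry: DetectorGeometry,
    orientation: Orientation | None = None,
    pad_factor: int = 2,
) -> DiffractionPattern:
    """Noiseless flat-Ewald intensities via the FFT fast path."""
    F = simulate_field_fft(particle, geometry, orientation, pad_factor)
    return DiffractionPattern(np.abs(F) ** 2, "noiseless", geometry, orientation)


def normalize_max(patterns):
    """Scale each pattern to maximum 1 (the common-maximum normalization).

    Accepts a single pattern or an iterable; returns the same structure.
    """
    single = isinstance(patterns, DiffractionPattern)
    items = [patterns] if single else list(patterns)
    out = []
    for p in items:
        m = p.values.max()
        if m <= 0:
            raise ValueError("cannot normalize an all-zero pattern")
        out.append(p.with_values(p.values / m))
    return out[0] if single else out


def downsample(pattern: DiffractionPattern, target_side: int, mode: str = "bin") -> DiffractionPattern:
    """Reduce resolution; sum-binning conserves total integrated intensity."""
    n = pattern.geometry.n_side
    if target_side > n:
        raise ValueError("target side larger than source")
    if mode == "bin":
        if n % target_side:
            raise ValueError("source side not divisible by target side for binning")
        f = n // target_side
        v = pattern.values.reshape(target_side, f, target_side, f).sum(axis=(1, 3))
    elif mode == "interp":
        from scipy.ndimage import zoom

        v = np.clip(zoom(pattern.values, target_side / n, order=1), 0.0, None)
    else:
        raise ValueError(f"unknown downsampling mode {mode!r}")
    geo = pattern.geometry.binned(n // target_side) if n % target_side == 0 else pattern.geometry
    return DiffractionPattern(v, pattern.state, geo, pattern.orientation)


def pattern_rng(seed: int, pattern_index: int = 0) -> np.random.Generator:
    """Independent stream per pattern from (global seed, pattern index)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(pattern_index)])


def poisson_corrupt(
    pattern: DiffractionPattern, noise: NoiseConfig, pattern_index: int = 0
) -> DiffractionPattern:
    """Photon-count pattern: K_i ~ Poisson(f * I_i), reproducible per seed."""
    if pattern.state != "noiseless":
        raise ValueError("poisson_corrupt expects a noiseless pattern")
    if pattern.values.max() > 1.0 + 1e-9:
        raise ValueError("pattern must be max-normalized before corruption")
    rng = pattern_rng(noise.seed, pattern_index)
    counts = rng.poisson(noise.intensity_factor * pattern.values).astype(float)
    return pattern.with_values(counts, state="noisy")
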