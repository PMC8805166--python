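"""Detector geometry, scattering-vector maps and orientations.

The detector is a square grid of ``n_side`` pixels normal to the beam at
distance ``distance`` from the interaction point.  The beam axis pierces the
detector at pixel ``(n_side // 2, n_side // 2)`` (array row/column order,
matching the centred-FFT convention), so one pixel lies exactly on the
forward direction for even grids.

The scattering vector of a pixel is q = (2*pi/lambda) * (s_hat - s0_hat)
with |q| = (4*pi/lambda) sin(theta); the exact Ewald-sphere mapping is the
default and a flat-Ewald (small-angle) approximation is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# hc in keV * m; lambda = HC_KEV_M / E[keV]
HC_KEV_M = 1.23984198e-9


@dataclass(frozen=True)
class DetectorGeometry:
    """Square pixel detector on the beam axis.

    Parameters
    ----------
    photon_energy : float
        Photon energy in keV.
    distance : float
        Sample-detector distance in metres.
    pixel_size : float
        Pixel edge in metres.
    n_side : int
        Pixels per detector edge; must be even.
    """

    photon_energy: float
    distance: float
    pixel_size: float
    n_side: int

    def __post_init__(self) -> None:
        if self.photon_energy <= 0:
            raise ValueError("photon_energy must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_side <= 0 or self.n_side % 2:
            raise ValueError("n_side must be a positive even integer")

    @property
    def wavelength(self) -> float:
        """X-ray wavelength in metres."""
        return HC_KEV_M / self.photon_energy

    @property
    def centre(self) -> tuple[int, int]:
        """(row, col) of the pixel on the beam axis."""
        return (self.n_side // 2, self.n_side // 2)

    def binned(self, factor: int) -> "DetectorGeometry":
        """Geometry of the same detector after ``factor`` x ``factor`` binning."""
        if self.n_side % factor:
            raise ValueError("n_side not divisible by binning factor")
        return DetectorGeometry(
            self.photon_energy,
            self.distance,
            self.pixel_size * factor,
            self.n_side // factor,
        )


# Paper-scale reference geometry: 8 keV, 15 cm, 128x128 with an effective
# 800 um pixel (a 200 um native detector binned down to 128 pixels), which
# puts the central-speckle statistics of 10-100 kDa particles in the
# 7-30 pixel range.
PAPER_GEOMETRY = DetectorGeometry(
    photon_energy=8.0, distance=0.15, pixel_size=800e-6, n_side=128
)


def detector_qmap(geometry: DetectorGeometry, flat_ewald: bool = False) -> np.ndarray:
    """Per-pixel scattering vectors, shape ``(n_side, n_side, 3)`` in 1/m.

    Component order is (q_row, q_col, q_beam).  With ``flat_ewald`` the
    curvature term along the beam is dropped (q_beam = 0) and the transverse
    components use the small-angle form 2*pi*x/(lambda*L).
    """
    n = geometry.n_side
    lam = geometry.wavelength
    c = n // 2
    idx = np.arange(n) - c
    y = idx[:, None] * geometry.pixel_size  # row offset on detector
    x = idx[None, :] * geometry.pixel_size  # col offset
    if flat_ewald:
        k = 2.0 * np.pi / (lam * geometry.distance)
        q = np.zeros((n, n, 3))
        q[..., 0] = k * y
        q[..., 1] = k * x
        return q
    L = geometry.distance
    r = np.sqrt(x * x + y * y + L * L)
    k = 2.0 * np.pi / lam
    q = np.empty((n, n, 3))
    q[..., 0] = k * (y / r)
    q[..., 1] = k * (x / r)
    q[..., 2] = k * (L / r - 1.0)
    return q


@dataclass(frozen=True)
class Orientation:
    """Particle orientation as a unit quaternion (w, x, y, z)."""

    quaternion: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components")
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("quaternion must be unit norm within 1e-9")

    @classmethod
    def identity(cls) -> "Orientation":
        return cls((1.0, 0.0, 0.0, 0.0))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Orientation":
        """Uniform orientation: normalized 4D Gaussian quaternion."""
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        if q[0] < 0:
            q = -q
        return cls(tuple(q))

    def as_matrix(self) -> np.ndarray:
        """3x3 rotation matrix (acts on column vectors)."""
        w, x, y, z = self.quaternion
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
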