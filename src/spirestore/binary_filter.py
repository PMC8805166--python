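"""Autocorrelation support filtering -- the benchmark denoiser.

The inverse Fourier transform of the diffraction intensities is the
spatial autocorrelation of the particle's scattering density.  For an
oversampled pattern the autocorrelation is compactly supported (twice the
particle extent), so zeroing everything outside that support and
transforming back projects the intensities onto the band-limited subspace
-- a matched low-pass filter.  With the support derived from the noiseless
simulated pattern this is a best-case ("almost optimal") benchmark; it is
deliberately not robust to missing-data regions, which are zero-filled
before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import DiffractionPattern


def _centred_ifft(values: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(values)))


def _centred_fft(values: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(values)))


@dataclass
class Support:
    """Boolean autocorrelation-space support (True = inside)."""

    inside: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 2 or self.inside.shape[0] != self.inside.shape[1]:
            raise ValueError("support must be a square 2D array")


def autocorrelation(pattern: DiffractionPattern | np.ndarray) -> np.ndarray:
    """Centred inverse transform of the intensities (complex array).

    For a noiseless Friedel-symmetric pattern the result is real to
    numerical precision; the central pixel equals mean(I) under numpy's
    1/N^2 inverse normalization.
    """
    values = pattern.values if isinstance(pattern, DiffractionPattern) else np.asarray(pattern)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("pattern must be square")
    return _centred_ifft(values)


def _centrosymmetrize(inside: np.ndarray) -> np.ndarray:
    """Union with the inversion partner about the centred-FFT origin."""
    flipped = np.flip(inside)
    for axis in (0, 1):
        flipped = np.roll(flipped, 1, axis=axis)
    return inside | flipped


def support_from_noiseless(
    noiseless: DiffractionPattern, threshold: float = 1e-4
) -> Support:
    """True support: pixels with |AC| >= threshold * max|AC|, symmetrized."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ac = np.abs(autocorrelation(noiseless))
    inside = ac >= threshold * ac.max()
    return Support(_centrosymmetrize(inside), threshold)


def binary_filter_project(values: np.ndarray, support: Support) -> np.ndarray:
    """Support projection without physicality clipping (real output)."""
    ac = _centred_ifft(np.asarray(values, dtype=float))
    filtered = _centred_fft(ac * support.inside)
    return filtered.real


def binary_filter_denoise(
    noisy: DiffractionPattern, support: Support, clip: bool = True
) -> DiffractionPattern:
    """Constrain the autocorrelation to the support and transform back.

    Masked pixels (if the pattern carries a mask) are zero-filled before
    the transform; negative back-transformed intensities are clipped to
    zero by default so the output is physical.
    """
    values = noisy.values
    if noisy.mask is not None:
        values = np.where(noisy.mask, 0.0, values)
    if values.shape != support.inside.shape:
        raise ValueError("pattern and support shapes differ")
    restored = binary_filter_project(values, support)
    if clip:
        restored = np.clip(restored, 0.0, None)
    return noisy.with_values(restored, state="restored")
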