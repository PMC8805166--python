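"""Evaluation metrics: linearized MSE, PSNR, speckle size, mask/speckle
ratio and the true-phase best-case reconstruction.

All errors are computed on the linear intensity scale with the noiseless
reference max-normalized to 1, so PSNR reduces to -10*log10(MSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import DiffractionPattern


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, DiffractionPattern) else np.asarray(x, dtype=float)


def mse(restored, reference, where: np.ndarray | None = None) -> float:
    """Mean squared error on the linear intensity scale.

    ``where`` restricts the average to a boolean pixel subset (e.g. the
    in-mask error); by default the full frame is used, matching how the
    masked-restoration distributions are reported.
    """
    a, b = _values(restored), _values(reference)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    d2 = (a - b) ** 2
    if where is not None:
        if where.shape != a.shape:
            raise ValueError("where-mask shape mismatch")
        if not where.any():
            raise ValueError("empty pixel subset")
        return float(d2[where].mean())
    return float(d2.mean())


def psnr_from_mse(mse_value: float) -> float:
    """Peak signal-to-noise ratio in dB for a unit-peak reference.

    PSNR = -10*log10(MSE).  MSE of exactly zero returns +inf.
    """
    if mse_value < 0:
        raise ValueError("mse must be non-negative")
    if mse_value == 0:
        return float("inf")
    return float(-10.0 * np.log10(mse_value))


def speckle_size(pattern, column: int | None = None, smooth: bool = False) -> float:
    """Vertical extent of the central speckle, in pixels.

    The distance between the first strict local minima above and below the
    central maximum along the central column.  Optional 3-point smoothing
    for noisy diagnostics (off by default; noiseless patterns need none).
    """
    v = _values(pattern)
    n = v.shape[0]
    col = v[:, n // 2 if column is None else column].astype(float)
    if smooth:
        col = np.convolve(col, np.ones(3) / 3.0, mode="same")
    # central maximum: brightest pixel in the middle half of the column
    lo, hi = n // 4, 3 * n // 4
    c = lo + int(np.argmax(col[lo:hi]))
    below = _walk_to_minimum(col, c, +1)
    above = _walk_to_minimum(col, c, -1)
    if below is None or above is None:
        raise ValueError("no local minima found: flat or degenerate pattern")
    return float(below - above)


def _walk_to_minimum(col: np.ndarray, start: int, step: int) -> int | None:
    """Index of the first strict local minimum walking from ``start``."""
    n = len(col)
    i = start + step
    while 0 < i < n - 1:
        if col[i] < col[i - step] and col[i] <= col[i + step]:
            return i
        i += step
    return None


def mask_speckle_ratio(mask_width: float, speckle: float) -> float:
    """Mask width over central-speckle size, the inpainting difficulty knob."""
    if speckle <= 0:
        raise ValueError("speckle size must be positive")
    return float(mask_width) / float(speckle)


def true_phase_reconstruction(intensities, true_phases: np.ndarray) -> np.ndarray:
    """Best-case real-space image: inverse transform of sqrt(I)*exp(i*phi).

    With noiseless intensities and the simulation's own phases this
    reproduces the (band-limited) projected scattering density exactly.
    Returns the real part of the centred inverse transform.
    """
    I = _values(intensities)
    if I.shape != true_phases.shape:
        raise ValueError("shape mismatch")
    amp = np.sqrt(np.clip(I, 0.0, None))
    F = amp * np.exp(1j * true_phases)
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(F)))
    return img.real


@dataclass
class MetricsResult:
    """Per-pattern MSE/PSNR values with distribution summaries."""

    mse_values: np.ndarray
    psnr_values: np.ndarray
    group: str = ""

    @property
    def mean_mse(self) -> float:
        return float(self.mse_values.mean())

    @property
    def median_mse(self) -> float:
        return float(np.median(self.mse_values))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.mse_values, [25, 75])
        return float(q1), float(q3)

    @property
    def mean_psnr(self) -> float:
        return float(self.psnr_values.mean())


def evaluate_dataset(restorations, references, masks=None, groups=None) -> dict[str, MetricsResult]:
    """Per-pattern MSE/PSNR, optionally grouped by condition label.

    ``groups`` is an optional sequence of labels (e.g. "f=10/stripe2"); the
    result maps each label to its distribution.  Without labels a single
    entry "all" is returned.
    """
    restorations = list(restorations)
    references = list(references)
    if not restorations:
        raise ValueError("empty input")
    if len(restorations) != len(references):
        raise ValueError("restorations and references must align")
    labels = list(groups) if groups is not None else ["all"] * len(restorations)
    out: dict[str, list[float]] = {}
    for r, ref, lab in zip(restorations, references, labels):
        out.setdefault(lab, []).append(mse(r, ref))
    return {
        lab: MetricsResult(
            np.asarray(v), np.asarray([psnr_from_mse(x) for x in v]), group=lab
        )
        for lab, v in out.items()
    }
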