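"""Log-scale normalization to [0, 1] and its exact inverse.

Diffraction intensities span many decades; before they are fed to the
restorer they are compressed with

    I_hat = log(1 + c * I) / log(1 + c * I_max)

which maps 0 -> 0 and the reference maximum -> 1, is strictly monotone,
and is exactly invertible given the stored reference maximum.  The
compression constant ``c`` sets how many decades are spread over [0, 1];
on photon counts c = 1 reproduces a plain log1p compression, and dataset
builders choose c equal to the intensity factor so that linearized counts
K/f are compressed exactly like raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import DiffractionPattern


@dataclass
class NormalizedPattern:
    """Pattern in normalized log space, with the inverse-transform metadata."""

    values: np.ndarray
    reference_max: float
    constant: float = 1.0
    state: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.reference_max <= 0:
            raise ValueError("reference_max must be positive")
        if self.constant <= 0:
            raise ValueError("compression constant must be positive")


def log_normalize(
    pattern: DiffractionPattern | np.ndarray,
    reference_max: float,
    constant: float = 1.0,
    clip: bool = False,
) -> NormalizedPattern:
    """Compress non-negative intensities into [0, 1] on a log scale.

    ``reference_max`` must bound the data (noisy inputs that exceed it can
    be clipped with ``clip=True``, e.g. K/f overshooting the unit maximum).
    """
    values = pattern.values if isinstance(pattern, DiffractionPattern) else np.asarray(pattern, float)
    if np.any(values < 0):
        raise ValueError("negative intensities cannot be log-normalized")
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    if values.max(initial=0.0) > reference_max * (1 + 1e-12):
        if clip:
            values = np.minimum(values, reference_max)
        else:
            raise ValueError("pattern exceeds reference_max; pass clip=True for noisy data")
    out = np.log1p(constant * values) / np.log1p(constant * reference_max)
    return NormalizedPattern(out, float(reference_max), float(constant))


def linearize(norm: NormalizedPattern) -> np.ndarray:
    """Exact inverse of :func:`log_normalize`; returns linear intensities.

    Values outside [0, 1] by more than 1e-6 (network overshoot) are clipped
    with a warning.
    """
    v = norm.values
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        warnings.warn("normalized values outside [0, 1] beyond tolerance; clipping", stacklevel=2)
    v = np.clip(v, 0.0, 1.0)
    return np.expm1(v * np.log1p(norm.constant * norm.reference_max)) / norm.constant
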