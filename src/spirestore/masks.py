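"""Missing-data masks: central stripe, circular beamstop and an emulated
AGIPD-like module-gap layout.

A mask is a boolean array with True marking pixels where no data were
recorded (module gaps, beamstop shadow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MASK_LABELS = ("stripe", "beamstop", "agipd_like", "custom", "none")


@dataclass
class Mask:
    """Boolean missing-pixel map; True = no data."""

    missing: np.ndarray
    label: str = "custom"
    width: int | None = None  # stripe width, pixels
    diameter: int | None = None  # beamstop diameter, pixels

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.ndim != 2 or self.missing.shape[0] != self.missing.shape[1]:
            raise ValueError("mask must be a square 2D array")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


def empty_mask(n_side: int) -> Mask:
    return Mask(np.zeros((n_side, n_side), dtype=bool), "none")


def stripe_mask(n_side: int, width: int) -> Mask:
    """Horizontal band of ``width`` full rows centred on the detector.

    The band occupies rows floor((n-w)/2) ... floor((n-w)/2)+w-1 (0-based).
    """
    if width < 0 or width > n_side:
        raise ValueError("stripe width must lie in [0, n_side]")
    m = np.zeros((n_side, n_side), dtype=bool)
    start = (n_side - width) // 2
    m[start : start + width, :] = True
    return Mask(m, "stripe", width=width)


def beamstop_mask(n_side: int, diameter: int) -> Mask:
    """Circular beamstop: pixels whose centre lies within diameter/2 of the
    inter-pixel detector centre are missing."""
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    c = (n_side - 1) / 2.0  # geometric centre of the pixel grid
    idx = np.arange(n_side) - c
    r2 = idx[:, None] ** 2 + idx[None, :] ** 2
    m = r2 <= (diameter / 2.0) ** 2
    return Mask(m, "beamstop", diameter=diameter)


def agipd_like_mask(n_side: int = 128) -> Mask:
    """Deterministic emulation of the AGIPD module-gap layout.

    The real detector is tiled from rectangular modules; the gaps between
    them form an asymmetric pattern of dead stripes.  At the reference
    128-pixel layout the emulation places:

    * a wide central horizontal gap, 14 rows tall on the left half and 8 on
      the right (so the widest missing band measured along the vertical
      axis is 14 pixels);
    * two lateral horizontal gaps (3 and 2 rows) at unequal distances from
      the centre, breaking mirror symmetry about the horizontal axis;
    * a segmented central vertical gap, 4 columns wide, interrupted at
      module boundaries so no vertical run exceeds 14 pixels.

    Other (even) sizes are scaled proportionally; the 14-pixel statistic is
    exact at n_side = 128.
    """
    if n_side % 2:
        raise ValueError("n_side must be even")
    s = n_side / 128.0

    def px(v: float) -> int:
        return int(round(v * s))

    m = np.zeros((n_side, n_side), dtype=bool)
    # central horizontal module gap: 14 rows on the left half, 8 on the right
    m[px(58) : px(72), : px(72)] = True
    m[px(61) : px(69), px(72) :] = True
    # lateral horizontal gaps, asymmetric about the centre row
    m[px(26) : px(29), :] = True
    m[px(97) : px(99), :] = True
    # segmented central vertical gap (cols 63-66): runs of <= 14 rows with
    # single-row breaks so no column accumulates a longer contiguous run
    c0, c1 = px(63), px(67)
    for r_lo, r_hi in ((0, 12), (13, 25), (30, 44), (45, 57), (73, 87),
                       (88, 96), (100, 114), (115, 128)):
        m[px(r_lo) : px(r_hi), c0:c1] = True
    # clear break rows inside the vertical gap next to the horizontal bands
    for r in (12, 29, 44, 57, 72, 87, 96, 99, 114):
        m[px(r), c0:c1] = False
    # short vertical stub on the upper half only (asymmetry marker)
    m[px(8) : px(20), px(30) : px(32)] = True
    return Mask(m, "agipd_like")


def apply_mask(values: np.ndarray, mask: Mask, fill: float = 0.0) -> np.ndarray:
    """Return a copy with missing pixels set to ``fill``."""
    values = np.asarray(values)
    if values.shape != mask.missing.shape:
        raise ValueError("pattern and mask shapes differ")
    out = values.copy()
    out[mask.missing] = fill
    return out


def widest_vertical_band(mask: Mask) -> int:
    """Longest contiguous run of missing pixels along any column."""
    best = 0
    for col in range(mask.missing.shape[1]):
        run = 0
        for v in mask.missing[:, col]:
            run = run + 1 if v else 0
            best = max(best, run)
    return best
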