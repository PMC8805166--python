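"""Synthetic dataset generation and HDF5 packaging.

A dataset emulates the published study conditions: one diffraction
pattern per particle (pseudo-protein blobs across 10-100 kDa by default,
geometric shapes or PDB files on request) at a uniformly random
orientation, max-normalized, Poisson-corrupted at one or more intensity
factors, optionally masked, and log-normalized for the restorer.  Splits
are disjoint and exhaustive; every array is reproducible from the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry, Orientation
from .masks import Mask, empty_mask
from .particles import Particle, blob_particle, read_pdb, shape_particle
from .preprocess import log_normalize
from .simulate import (
    DiffractionPattern,
    NoiseConfig,
    downsample,
    normalize_max,
    pattern_rng,
    poisson_corrupt,
    simulate_pattern,
    simulate_pattern_fft,
    simulate_field_fft,
)

#: Default generator geometry: 8 keV, 15 cm, 128x128 output with an
#: effective 800 um pixel, simulated at a 256-pixel native grid (400 um)
#: and sum-binned 2x2 so neighbouring local maxima are averaged as they
#: are when a finer detector is downsampled.
DEFAULT_NATIVE = DetectorGeometry(8.0, 0.15, 400e-6, 256)
DEFAULT_BIN = 2


@dataclass
class DatasetSpec:
    """Recipe for a packaged dataset."""

    n_patterns: int
    source: str = "blob"  # blob | shapes | pdb_files
    weight_range_kda: tuple[float, float] = (10.0, 100.0)
    intensity_factors: tuple[float, ...] = (10.0,)
    mask: Mask | None = None
    geometry: DetectorGeometry = field(default_factory=lambda: DEFAULT_NATIVE)
    bin_factor: int = DEFAULT_BIN
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train/val/test
    seed: int = 0
    engine: str = "fft"  # fft (flat-Ewald fast path) | direct (exact Ewald)
    pdb_paths: tuple[str, ...] = ()
    shape_size: float = 4e-9
    shape_density: float = 1.35

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if self.source not in ("blob", "shapes", "pdb_files"):
            raise ValueError(f"unknown particle source {self.source!r}")
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.engine not in ("fft", "direct"):
            raise ValueError("engine must be 'fft' or 'direct'")
        if any(f <= 0 for f in self.intensity_factors):
            raise ValueError("intensity factors must be positive")

    @property
    def output_side(self) -> int:
        return self.geometry.n_side // self.bin_factor

    def split_indices(self) -> dict[str, np.ndarray]:
        """Disjoint, exhaustive train/val/test index sets (deterministic)."""
        n = self.n_patterns
        n_train = int(round(n * self.splits[0]))
        n_val = int(round(n * self.splits[1]))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        idx = np.arange(n)
        return {
            "train": idx[:n_train],
            "val": idx[n_train : n_train + n_val],
            "test": idx[n_train + n_val :],
        }


@dataclass
class Dataset:
    """In-memory dataset: aligned arrays plus provenance."""

    spec: DatasetSpec
    noiseless: np.ndarray  # (N, n, n), each max-normalized to 1
    noisy: dict[float, np.ndarray]  # factor -> (N, n, n) photon counts
    phases: np.ndarray  # (N, n, n) true phases at the output grid
    quaternions: np.ndarray  # (N, 4)
    mask: Mask

    @property
    def n_patterns(self) -> int:
        return self.noiseless.shape[0]

    def splits(self) -> dict[str, np.ndarray]:
        return self.spec.split_indices()

    def training_pairs(
        self, factor: float | None = None, subset: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(corrupted normalized input, clean normalized target) arrays.

        Noisy counts are linearized to K/f, masked pixels zero-filled in
        normalized space, and both sides share the global unit reference
        maximum with compression constant c = f (so counts compress as
        log1p(K)); for the noiseless-mask-only study (factor None) a fixed
        c = 1000 gives comparable dynamic-range compression.
        """
        idx = self.splits()[subset] if subset else np.arange(self.n_patterns)
        clean = self.noiseless[idx]
        if factor is None:
            c = 1000.0
            corrupted = clean.copy()
        else:
            c = float(factor)
            corrupted = self.noisy[factor][idx] / factor
        targets = log_normalize(clean.reshape(-1), 1.0, constant=c).values.reshape(clean.shape)
        inputs = log_normalize(
            corrupted.reshape(-1), 1.0, constant=c, clip=True
        ).values.reshape(corrupted.shape)
        if self.mask.n_missing:
            inputs[:, self.mask.missing] = 0.0
        return inputs, targets

    def audit(self) -> None:
        """Self-check: ranges, alignment, split disjointness, metadata."""
        n = self.n_patterns
        side = self.spec.output_side
        assert self.noiseless.shape == (n, side, side)
        assert np.allclose(self.noiseless.max(axis=(1, 2)), 1.0)
        assert self.noiseless.min() >= 0
        for f, arr in self.noisy.items():
            assert arr.shape == (n, side, side)
            assert np.all(arr >= 0) and np.all(arr == np.rint(arr))
        assert self.phases.shape == (n, side, side)
        assert self.quaternions.shape == (n, 4)
        assert np.allclose(np.linalg.norm(self.quaternions, axis=1), 1.0)
        assert self.mask.missing.shape == (side, side)
        sp = self.splits()
        all_idx = np.concatenate([sp["train"], sp["val"], sp["test"]])
        assert len(np.unique(all_idx)) == n == len(all_idx)


def _make_particle(spec: DatasetSpec, k: int, rng: np.random.Generator) -> Particle:
    if spec.source == "blob":
        lo, hi = spec.weight_range_kda
        w = float(rng.uniform(lo, hi))
        return blob_particle(w, seed=int(rng.integers(0, 2**31 - 1)))
    if spec.source == "shapes":
        kind = ("sphere", "cube", "icosahedron")[k % 3]
        return shape_particle(kind, spec.shape_size, spec.shape_density)
    return read_pdb(spec.pdb_paths[k % len(spec.pdb_paths)])


def build_dataset(spec: DatasetSpec) -> Dataset:
    """Simulate, normalize, corrupt and package one dataset."""
    n_out = spec.output_side
    noiseless = np.empty((spec.n_patterns, n_out, n_out))
    phases = np.empty_like(noiseless)
    quats = np.empty((spec.n_patterns, 4))
    out_geometry = spec.geometry.binned(spec.bin_factor)
    for k in range(spec.n_patterns):
        rng = pattern_rng(spec.seed, k)
        particle = _make_particle(spec, k, rng)
        orientation = Orientation.random(rng)
        quats[k] = orientation.quaternion
        if spec.engine == "fft":
            native = simulate_pattern_fft(particle, spec.geometry, orientation)
        else:
            native = simulate_pattern(particle, spec.geometry, orientation)
        pat = downsample(native, n_out) if spec.bin_factor > 1 else native
        noiseless[k] = normalize_max(pat).values
        # true phases sampled on the output grid (unbinned field)
        phases[k] = np.angle(simulate_field_fft(particle, out_geometry, orientation))
    noisy: dict[float, np.ndarray] = {}
    for f in spec.intensity_factors:
        counts = np.empty_like(noiseless)
        for k in range(spec.n_patterns):
            pat = DiffractionPattern(noiseless[k], "noiseless", out_geometry)
            counts[k] = poisson_corrupt(
                pat, NoiseConfig(f, seed=spec.seed + 1), pattern_index=k
            ).values
        noisy[f] = counts
    mask = spec.mask if spec.mask is not None else empty_mask(n_out)
    ds = Dataset(spec, noiseless, noisy, phases, quats, mask)
    ds.audit()
    return ds


# ------------------------------------------------------------------ HDF5


def save_hdf5(dataset: Dataset, path: str | os.PathLike) -> None:
    """Layout: /noiseless, /noisy/f<factor>, /phases, /mask, /meta attrs."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("noiseless", data=dataset.noiseless, compression="gzip")
        g = h5.create_group("noisy")
        for f, arr in dataset.noisy.items():
            g.create_dataset(f"f{f:g}", data=arr, compression="gzip")
        h5.create_dataset("phases", data=dataset.phases, compression="gzip")
        h5.create_dataset("mask", data=dataset.mask.missing)
        h5.create_dataset("quaternions", data=dataset.quaternions)
        meta = h5.create_group("meta")
        s = dataset.spec
        meta.attrs.update(
            {
                "n_patterns": s.n_patterns,
                "source": s.source,
                "weight_range_kda": list(s.weight_range_kda),
                "intensity_factors": list(s.intensity_factors),
                "photon_energy_kev": s.geometry.photon_energy,
                "distance_m": s.geometry.distance,
                "pixel_size_m": s.geometry.pixel_size,
                "native_side": s.geometry.n_side,
                "bin_factor": s.bin_factor,
                "splits": list(s.splits),
                "seed": s.seed,
                "engine": s.engine,
                "mask_label": dataset.mask.label,
            }
        )
        for name, idx in dataset.splits().items():
            meta.create_dataset(f"split_{name}", data=idx)


def load_hdf5(path: str | os.PathLike) -> Dataset:
    import h5py

    with h5py.File(path, "r") as h5:
        meta = h5["meta"].attrs
        geometry = DetectorGeometry(
            float(meta["photon_energy_kev"]),
            float(meta["distance_m"]),
            float(meta["pixel_size_m"]),
            int(meta["native_side"]),
        )
        spec = DatasetSpec(
            n_patterns=int(meta["n_patterns"]),
            source=str(meta["source"]),
            weight_range_kda=tuple(meta["weight_range_kda"]),
            intensity_factors=tuple(meta["intensity_factors"]),
            geometry=geometry,
            bin_factor=int(meta["bin_factor"]),
            splits=tuple(meta["splits"]),
            seed=int(meta["seed"]),
            engine=str(meta["engine"]),
        )
        noisy = {
            float(name[1:]): h5["noisy"][name][...] for name in h5["noisy"]
        }
        mask = Mask(h5["mask"][...], str(meta["mask_label"]))
        ds = Dataset(
            spec,
            h5["noiseless"][...],
            noisy,
            h5["phases"][...],
            h5["quaternions"][...],
            mask,
        )
    return ds
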