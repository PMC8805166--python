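"""Particle models: atomic point sets, filled geometric shapes and
pseudo-protein blobs.

Every particle is reduced to a weighted 3D point cloud; the forward
simulator only ever sees points and scattering weights.  Atomic weights
default to the atomic number Z (no q-dependent form factors, no anomalous
terms) -- sufficient for a restoration study where absolute photon counts
are set by the intensity factor, not by sub-percent scattering physics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

ANGSTROM = 1e-10

# Avogadro and unit conversions for density -> scattering-mass bookkeeping
_AVOGADRO = 6.02214076e23
_DA_PER_KDA = 1000.0

#: Globular-protein mass-radius scaling, R[m] = _PROTEIN_R0 * (M[kDa])**(1/3).
#: Calibrated so a 50 kDa protein has a ~4.9 nm diameter.
_PROTEIN_R0 = 0.66e-9

#: Heavy-atom-scale points per kDa for pseudo-proteins (one residue is
#: ~110 Da and carries ~8 non-hydrogen atoms).
_POINTS_PER_KDA = 110.0 / 1.3

SHAPE_KINDS = ("sphere", "cube", "icosahedron")


@dataclass
class Particle:
    """Weighted point cloud in metres.

    ``kind`` records provenance: "atoms" (PDB), "blob" (pseudo-protein),
    or one of the geometric shapes.
    """

    kind: str
    positions: np.ndarray  # (N, 3) metres
    weights: np.ndarray  # (N,) dimensionless
    size: float | None = None  # metres, shapes only
    density: float | None = None  # g/cm^3, shapes only
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.positions.shape[0] == 0:
            raise ValueError("particle has no points")
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.weights.shape[0] != self.positions.shape[0]:
            raise ValueError("weights and positions must align")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.size is not None and self.size <= 0:
            raise ValueError("size must be positive")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def radius(self) -> float:
        """Maximum distance of any point from the centre of mass, metres."""
        com = np.average(self.positions, axis=0, weights=self.weights)
        return float(np.linalg.norm(self.positions - com, axis=1).max())

    def centred(self) -> "Particle":
        com = np.average(self.positions, axis=0, weights=self.weights)
        return Particle(
            self.kind, self.positions - com, self.weights, self.size, self.density, self.label
        )


def blob_radius(weight_kda: float) -> float:
    """Globular radius (m) for a protein of the given molecular weight."""
    return _PROTEIN_R0 * weight_kda ** (1.0 / 3.0)


def blob_particle(weight_kda: float, seed: int) -> Particle:
    """Pseudo-protein: a compact, slightly anisotropic random point cloud.

    The point count scales linearly with molecular weight and the radius
    follows the cube-root mass-radius law of globular proteins, so blobs
    across 10-100 kDa reproduce the speckle-size spread of a real protein
    ensemble.  Deterministic per (weight, seed).
    """
    if weight_kda <= 0:
        raise ValueError("weight_kda must be positive")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5B10B])
    n = max(8, int(round(weight_kda * _POINTS_PER_KDA)))
    r0 = blob_radius(weight_kda)
    # mild random axis stretch for realistic anisotropy (drawn first so the
    # same seed gives the same shape across molecular weights)
    stretch = rng.uniform(0.8, 1.25, size=3)
    stretch *= (1.0 / np.prod(stretch)) ** (1.0 / 3.0)  # volume-preserving
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(n) ** (1.0 / 3.0)
    pts = v * (u * r0)[:, None] * stretch[None, :]
    w = np.full(n, 7.0)  # mean heavy-atom Z scale; absolute scale is normalized away
    return Particle("blob", pts, w, label=f"blob_{weight_kda:g}kDa_s{seed}")


def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v[0])  # circumscribed radius 1


def _inside_icosahedron(pts: np.ndarray) -> np.ndarray:
    """Points inside the regular icosahedron with circumscribed radius 1."""
    verts = _icosahedron_vertices()
    # face normals = normalized centroids of vertex triples forming faces;
    # equivalently all unit vectors (+-1,+-1,+-1)/sqrt3 and (0,+-1/phi,+-phi)/n
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    normals = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                normals.append((sx, sy, sz))
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            normals += [(0.0, a / phi, b), (a / phi, b, 0.0), (b, 0.0, a / phi)]
    normals = np.array(normals, dtype=float)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # inradius of icosahedron with circumradius 1
    inr = phi ** 2 / np.sqrt(3.0) / np.sqrt(phi * np.sqrt(5.0))
    return np.all(pts @ normals.T <= inr + 1e-12, axis=1)


def shape_particle(
    kind: str,
    size: float,
    density: float = 1.35,
    points_per_axis: int = 24,
    seed: int | None = None,
) -> Particle:
    """Uniform-density filled shape as a point cloud.

    ``size`` is the edge length (cube), diameter (sphere) or vertex-to-vertex
    diameter (icosahedron), in metres.  Points sit on a jittered regular grid
    filling the shape; total weight equals density * volume expressed in
    kDa-equivalent scattering mass, so weights scale with volume x density.
    """
    if kind not in SHAPE_KINDS:
        raise ValueError(f"unknown shape kind {kind!r}; expected one of {SHAPE_KINDS}")
    if size <= 0:
        raise ValueError("size must be positive")
    half = size / 2.0
    ax = (np.arange(points_per_axis) + 0.5) / points_per_axis * size - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if seed is not None:
        rng = np.random.default_rng(seed)
        pts = pts + rng.uniform(-0.5, 0.5, pts.shape) * (size / points_per_axis)
    if kind == "sphere":
        keep = np.linalg.norm(pts, axis=1) <= half
        volume = 4.0 / 3.0 * np.pi * half ** 3
    elif kind == "cube":
        keep = np.all(np.abs(pts) <= half, axis=1)
        volume = size ** 3
    else:  # icosahedron, circumscribed radius = half
        keep = _inside_icosahedron(pts / half)
        phi = (1.0 + np.sqrt(5.0)) / 2.0
        volume = 5.0 / 12.0 * (3.0 + np.sqrt(5.0)) * (2.0 * half / np.sqrt(phi * np.sqrt(5.0))) ** 3
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("degenerate shape: no points sampled")
    # scattering mass in kDa: density [g/cm^3] * volume [m^3] -> Da
    mass_da = density * 1e6 * volume * _AVOGADRO  # g/cm^3 * cm^3 -> g -> Da via N_A
    w = np.full(pts.shape[0], mass_da / _DA_PER_KDA / pts.shape[0])
    return Particle(kind, pts, w, size=size, density=density, label=kind)


def read_pdb(path: str | os.PathLike) -> Particle:
    """Read ATOM/HETATM records from a PDB file into a point cloud.

    First model only; alternate locations resolved to the highest-occupancy
    conformer; coordinates converted from Angstrom to metres; weights are
    atomic numbers.
    """
    import gemmi

    try:
        structure = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparsable PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"no models in PDB file {path}")
    model = structure[0]
    positions, weights = [], []
    for chain in model:
        for residue in chain:
            best: dict[str, object] = {}
            for atom in residue:
                if atom.element.atomic_number == 0:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:  # type: ignore[attr-defined]
                    best[atom.name] = atom
            for atom in best.values():
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                weights.append(float(atom.element.atomic_number))
    if not positions:
        raise ValueError(f"no ATOM/HETATM coordinates found in {path}")
    pts = np.asarray(positions) * ANGSTROM
    return Particle("atoms", pts, np.asarray(weights), label=os.path.basename(os.fspath(path)))
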