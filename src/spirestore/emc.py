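"""Orientation recovery by expand-maximize-compress (EMC).

Each 2D pattern is a slice of an unknown 3D Fourier intensity model at an
unknown orientation.  EMC treats the orientation as a latent variable on a
fixed rotation grid and alternates: expand (interpolate reference slices
from the model), maximize (posterior responsibilities of every rotation
for every pattern under a photon-count Poisson likelihood, or a Gaussian
likelihood for continuous restored intensities), and compress (tomographic
re-insertion of the patterns weighted by the responsibilities).

The blurred variant convolves the model with a sub-Shannon 3D Gaussian
after each compression, spreading every measured pixel over neighbouring
voxels to increase inter-pattern overlap in data-starved regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.special import logsumexp

from .geometry import DetectorGeometry, Orientation, detector_qmap
from .masks import Mask


# --------------------------------------------------------------- rotations


@dataclass
class RotationSet:
    """Quasi-uniform unit quaternions with quadrature weights summing to 1."""

    quaternions: np.ndarray  # (M, 4), scalar-first
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    def matrices(self) -> np.ndarray:
        return np.stack([_quat_to_matrix(q) for q in self.quaternions])


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_angle(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Angular distance (radians) between rotations, broadcasting over rows."""
    d = np.abs(np.sum(q1 * q2, axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


def sample_rotations(order: int) -> RotationSet:
    """Deterministic quasi-uniform SO(3) sampling (super-Fibonacci spiral).

    ``order`` scales the number of rotations as 30 * order**2 + 1; the set
    always contains the identity, and the covering radius shrinks as the
    order grows.  Equal quadrature weights.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n = 30 * order * order
    s = np.arange(n) + 0.5
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041  # positive root of x^4 = x + 4
    t = s / n
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    rr = np.sqrt(1.0 - t)
    alpha = d / phi
    beta = d / psi
    q = np.column_stack(
        [r * np.sin(alpha), r * np.cos(alpha), rr * np.sin(beta), rr * np.cos(beta)]
    )
    q = np.vstack([[1.0, 0.0, 0.0, 0.0], q])
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w = np.full(q.shape[0], 1.0 / q.shape[0])
    return RotationSet(q, w)


def mean_grid_spacing(rotations: RotationSet) -> float:
    """Mean nearest-neighbour angular distance (radians) over the grid."""
    q = rotations.quaternions
    # |q1.q2| gives cos(theta/2); nearest neighbour = largest |dot| != self
    dots = np.abs(q @ q.T)
    np.fill_diagonal(dots, -1.0)
    nn = np.clip(dots.max(axis=1), -1.0, 1.0)
    return float(np.mean(2.0 * np.arccos(nn)))


# ------------------------------------------------------------------ model


@dataclass
class FourierModel:
    """3D intensity model W on a cubic voxel grid with insertion weights."""

    voxels: np.ndarray
    weights: np.ndarray
    voxel_size: float  # 1/m, matched to the detector q-map

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape != self.weights.shape:
            raise ValueError("voxels and weights must be matching 3D arrays")

    @property
    def n_side(self) -> int:
        return self.voxels.shape[0]

    def n_empty(self) -> int:
        """Voxels never touched by any insertion."""
        return int(np.sum(self.weights <= 0))


@dataclass
class EMCConfig:
    """EMC run configuration.

    ``likelihood`` selects Poisson (photon counts) or Gaussian (continuous
    restored intensities, scale ``sigma``).  ``blur_sigma`` (voxels) enables
    the blurred variant; it should stay below the Shannon-pixel equivalent
    on the model grid.  ``interp`` chooses the slice/insertion kernel:
    "trilinear" (default) or "nearest" (for which the M step is the exact
    EM maximizer, giving strictly monotone likelihood).
    """

    likelihood: str = "poisson"
    sigma: float | None = None
    gaussian_weighting: str = "intensity"  # "intensity" | "uniform"
    blur_sigma: float = 0.0
    iterations: int = 20
    rotation_order: int = 3
    model_side: int = 32
    supersample: int = 2
    seed: int = 0
    interp: str = "trilinear"
    anneal_sigma: bool = True
    sigma_anneal_start: float = 6.0
    sigma_anneal_decay: float = 0.9
    init: str = "average"  # "average" | "random"

    def __post_init__(self) -> None:
        if self.likelihood not in ("poisson", "gaussian"):
            raise ValueError("likelihood must be 'poisson' or 'gaussian'")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.interp not in ("trilinear", "nearest"):
            raise ValueError("interp must be 'trilinear' or 'nearest'")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.gaussian_weighting not in ("intensity", "uniform"):
            raise ValueError("gaussian_weighting must be 'intensity' or 'uniform'")
        if self.init not in ("average", "random"):
            raise ValueError("init must be 'average' or 'random'")


@dataclass
class ResponsibilityMatrix:
    """Posterior P[k, j] of rotation j given pattern k; rows sum to 1."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("responsibilities must be non-negative")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("responsibility rows must sum to 1")
        self.probabilities = p

    def modes(self) -> np.ndarray:
        """Most responsible rotation index per pattern."""
        return np.argmax(self.probabilities, axis=1)


# ---------------------------------------------------- detector <-> voxels


def detector_voxel_coords(
    geometry: DetectorGeometry, model_side: int, supersample: int = 1,
    flat_ewald: bool = True,
) -> tuple[np.ndarray, float]:
    """Detector q-map in voxel units (origin at the grid centre).

    The voxel size is the detector's transverse q-spacing divided by
    ``supersample``: finer voxels reduce the trilinear interpolation error
    of slicing/insertion, which must stay below the inter-orientation
    intensity contrast for rotations to be distinguishable.  ``model_side``
    must cover the rotated detector footprint.
    """
    q = detector_qmap(geometry, flat_ewald=flat_ewald).reshape(-1, 3)
    dq = 2.0 * np.pi * geometry.pixel_size / (geometry.wavelength * geometry.distance)
    dq /= supersample
    qv = q / dq
    rmax = np.linalg.norm(qv, axis=1).max()
    if rmax > model_side / 2.0 - 1.0:
        raise ValueError(
            f"detector footprint (radius {rmax:.1f} voxels) exceeds the "
            f"{model_side}^3 model grid; enlarge model_side or crop the detector"
        )
    return qv, dq


def expand(
    model: FourierModel,
    rotations: RotationSet,
    geometry: DetectorGeometry,
    interp: str = "trilinear",
    supersample: int = 1,
) -> np.ndarray:
    """Reference slices: (M, n_pix) interpolated on each rotated Ewald surface."""
    qv, _ = detector_voxel_coords(geometry, model.n_side, supersample)
    c = model.n_side / 2.0
    ns = model.n_side
    slices = np.empty((len(rotations), qv.shape[0]))
    for j, R in enumerate(rotations.matrices()):
        # particle rotated by R means the detector samples W at R^T q
        coords = (qv @ R) + c
        if interp == "nearest":
            # same rounding as the insertion splat, so expand and compress
            # share one pixel-to-voxel assignment (exact EM pairing)
            idx = np.rint(coords).astype(int)
            np.clip(idx, 0, ns - 1, out=idx)
            slices[j] = model.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        else:
            slices[j] = map_coordinates(model.voxels, coords.T, order=1, mode="nearest")
    return np.clip(slices, 0.0, None)


def responsibilities(
    patterns: np.ndarray,
    slices: np.ndarray,
    config: EMCConfig,
    mask: Mask | None = None,
    prior: np.ndarray | None = None,
    sigma: float | None = None,
) -> tuple[ResponsibilityMatrix, float]:
    """E step: posterior over rotations per pattern and the mean
    log-likelihood log p(K_k) = logsumexp_j [log w_j + log L_jk].

    Poisson: sum_i K_i log W_i - W_i over unmasked pixels (W floored at a
    small epsilon).  Gaussian: -sum_i (K_i - W_i)^2 / (2 sigma^2 s_i) with
    per-pixel scale s_i = W_i + eps under the default intensity weighting
    (photon noise grows with intensity; a uniform scale would let the
    bright central speckle drown the orientation contrast of the outer
    speckles) or s_i = 1 under "uniform".
    """
    K = np.asarray(patterns, dtype=float).reshape(len(patterns), -1)
    W = np.asarray(slices, dtype=float)
    keep = None
    if mask is not None:
        keep = ~mask.missing.ravel()
        K = K[:, keep]
        W = W[:, keep]
    if config.likelihood == "poisson":
        eps = 1e-10
        logW = np.log(W + eps)
        logL = K @ logW.T - W.sum(axis=1)[None, :]  # (N, M)
    else:
        s = sigma if sigma is not None else config.sigma
        if s is None:
            s = estimate_gaussian_sigma(K, config.gaussian_weighting)
        if config.gaussian_weighting == "intensity":
            eps = 1e-3 * max(W.mean(), 1e-300)
            sw = W + eps  # (M, n_pix) per-pixel variance scale
            k2 = K * K
            logL = -(
                k2 @ (1.0 / sw).T
                - 2.0 * K @ (W / sw).T
                + (W * W / sw).sum(axis=1)[None, :]
            ) / (2.0 * s * s)
        else:
            k2 = np.sum(K * K, axis=1)[:, None]
            w2 = np.sum(W * W, axis=1)[None, :]
            logL = -(k2 + w2 - 2.0 * K @ W.T) / (2.0 * s * s)
    logprior = np.log(prior) if prior is not None else 0.0
    logpost = logL + logprior
    norm = logsumexp(logpost, axis=1, keepdims=True)
    P = np.exp(logpost - norm)
    P /= P.sum(axis=1, keepdims=True)
    return ResponsibilityMatrix(P), float(np.mean(norm))


def estimate_gaussian_sigma(patterns: np.ndarray, weighting: str = "intensity") -> float:
    """Data-driven Gaussian noise scale: median per-pattern RMS deviation
    from the ensemble-mean pattern (under the configured per-pixel
    variance weighting)."""
    K = np.asarray(patterns, dtype=float).reshape(len(patterns), -1)
    mean = K.mean(axis=0, keepdims=True)
    resid = K - mean
    if weighting == "intensity":
        eps = 1e-3 * max(mean.mean(), 1e-300)
        resid = resid / np.sqrt(mean + eps)
    return float(np.median(np.sqrt(np.mean(resid * resid, axis=1)))) or 1.0


def maximize_compress(
    patterns: np.ndarray,
    resp: ResponsibilityMatrix,
    rotations: RotationSet,
    geometry: DetectorGeometry,
    model_side: int = 32,
    mask: Mask | None = None,
    interp: str = "trilinear",
    supersample: int = 1,
) -> FourierModel:
    """M + C steps: responsibility-weighted tomographic insertion.

    Every pattern is inserted at every rotation with weight P[k, j]; voxel
    values are the weighted means of all contributing pixels.  Masked
    pixels contribute neither value nor weight.
    """
    K = np.asarray(patterns, dtype=float).reshape(len(patterns), -1)
    qv, dq = detector_voxel_coords(geometry, model_side, supersample)
    keep = np.ones(qv.shape[0], dtype=bool)
    if mask is not None:
        keep = ~mask.missing.ravel()
    qv = qv[keep]
    K = K[:, keep]
    P = resp.probabilities
    num = np.zeros((model_side,) * 3)
    den = np.zeros((model_side,) * 3)
    c = model_side / 2.0
    # per-rotation pixel-wise weighted sums over patterns
    pix_num = P.T @ K  # (M, n_pix)
    pix_den = P.sum(axis=0)  # (M,)
    for j, R in enumerate(rotations.matrices()):
        if pix_den[j] <= 1e-300:
            continue
        coords = (qv @ R) + c
        _splat(num, den, coords, pix_num[j], np.full(qv.shape[0], pix_den[j]), interp)
    voxels = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return FourierModel(voxels, den, dq)


def _splat(
    num: np.ndarray,
    den: np.ndarray,
    coords: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray,
    interp: str,
) -> None:
    n = num.shape[0]
    if interp == "nearest":
        idx = np.rint(coords).astype(int)
        np.clip(idx, 0, n - 1, out=idx)
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), num.shape)
        np.add.at(num.ravel(), flat, values)
        np.add.at(den.ravel(), flat, weights)
        return
    i0 = np.floor(coords).astype(int)
    f = coords - i0
    for dx in (0, 1):
        wx = (1 - f[:, 0]) if dx == 0 else f[:, 0]
        for dy in (0, 1):
            wy = (1 - f[:, 1]) if dy == 0 else f[:, 1]
            for dz in (0, 1):
                wz = (1 - f[:, 2]) if dz == 0 else f[:, 2]
                w = wx * wy * wz
                ix = np.clip(i0[:, 0] + dx, 0, n - 1)
                iy = np.clip(i0[:, 1] + dy, 0, n - 1)
                iz = np.clip(i0[:, 2] + dz, 0, n - 1)
                flat = np.ravel_multi_index((ix, iy, iz), num.shape)
                np.add.at(num.ravel(), flat, values * w)
                np.add.at(den.ravel(), flat, weights * w)


def blur_model(model: FourierModel, blur_sigma: float) -> FourierModel:
    """3D Gaussian convolution of voxels and weights; conserves totals."""
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    if blur_sigma == 0:
        return model
    # blur the accumulated intensity mass, not the ratio, so the weighted
    # mean stays consistent and empty gaps are filled by neighbours
    num = gaussian_filter(model.voxels * model.weights, blur_sigma, mode="constant")
    den = gaussian_filter(model.weights, blur_sigma, mode="constant")
    voxels = np.where(den > 1e-300, num / np.where(den > 1e-300, den, 1.0), 0.0)
    return FourierModel(voxels, den, model.voxel_size)


def shannon_pixel_voxels(particle_diameter: float, geometry: DetectorGeometry) -> float:
    """Shannon (critical) sampling interval in detector pixels == voxels.

    lambda * L / (2 * D * pixel) detector pixels; on the model grid one
    detector pixel is one voxel, so the same number bounds blur_sigma.
    """
    return geometry.wavelength * geometry.distance / (
        2.0 * particle_diameter * geometry.pixel_size
    )


@dataclass
class EMCResult:
    model: FourierModel
    responsibilities: ResponsibilityMatrix
    log_likelihood: list[float]
    rotations: RotationSet
    sigma_schedule: list[float] = field(default_factory=list)

    def estimated_quaternions(self) -> np.ndarray:
        return self.rotations.quaternions[self.responsibilities.modes()]


def run_emc(
    patterns: np.ndarray,
    config: EMCConfig,
    geometry: DetectorGeometry,
    mask: Mask | None = None,
    rotations: RotationSet | None = None,
) -> EMCResult:
    """Iterate expand -> responsibilities -> maximize_compress (-> blur).

    The model is initialized, by default, from the orientation-averaged
    insertion of all patterns with uniform responsibilities ("average"),
    or from a seeded random field ("random").  For the Gaussian
    likelihood, sigma is annealed geometrically from
    ``sigma_anneal_start`` times its (estimated) scale down to 1x, a
    deterministic-annealing schedule that delays hard orientation
    assignment while the model forms.

    Ab initio convergence is data-hungry: like the published full-scale
    studies, desk-scale runs from uninformed starts can settle in
    self-consistent local optima; see docs for the warm-start and
    held-out protocols used to validate orientation accuracy.
    """
    K = np.asarray(patterns, dtype=float)
    if K.ndim != 3 or K.shape[0] < 2:
        raise ValueError("need at least 2 patterns, shape (N, n, n)")
    rot = rotations if rotations is not None else sample_rotations(config.rotation_order)
    rng = np.random.default_rng(config.seed)
    ns = config.model_side
    _, dq = detector_voxel_coords(geometry, ns, config.supersample)
    if config.init == "average":
        uniform = ResponsibilityMatrix(np.full((len(K), len(rot)), 1.0 / len(rot)))
        model = maximize_compress(
            K, uniform, rot, geometry, ns, mask, config.interp, config.supersample
        )
    else:
        scale = K.mean() if K.mean() > 0 else 1.0
        model = FourierModel(
            scale * rng.exponential(size=(ns, ns, ns)), np.ones((ns, ns, ns)), dq
        )
    sigma0 = None
    if config.likelihood == "gaussian":
        sigma0 = (
            config.sigma
            if config.sigma is not None
            else estimate_gaussian_sigma(K, config.gaussian_weighting)
        )
    ll_history: list[float] = []
    sig_history: list[float] = []
    resp = None
    for it in range(config.iterations):
        slices = expand(model, rot, geometry, config.interp, config.supersample)
        sigma = None
        if sigma0 is not None:
            if config.anneal_sigma:
                factor = max(1.0, config.sigma_anneal_start * config.sigma_anneal_decay ** it)
                sigma = sigma0 * factor
            else:
                sigma = sigma0
            sig_history.append(sigma)
        resp, ll = responsibilities(K, slices, config, mask, rot.weights, sigma)
        if not np.isfinite(ll):
            raise FloatingPointError(f"EMC diverged (non-finite likelihood) at iteration {it}")
        ll_history.append(ll)
        model = maximize_compress(
            K, resp, rot, geometry, ns, mask, config.interp, config.supersample
        )
        if config.blur_sigma > 0:
            model = blur_model(model, config.blur_sigma)
    return EMCResult(model, resp, ll_history, rot, sig_history)


# --------------------------------------------------------- error scoring


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def orient_against_model(
    patterns: np.ndarray,
    model: FourierModel,
    rotations: RotationSet,
    geometry: DetectorGeometry,
    config: EMCConfig,
    mask: Mask | None = None,
) -> np.ndarray:
    """Most-probable rotation per pattern given a fixed Fourier model.

    The orientation-determination half of EMC on its own: used to orient
    new patterns against a previously assembled model (and, in testing, to
    validate orientation accuracy on patterns held out from the model).
    Returns the quaternions of the posterior modes.
    """
    slices = expand(model, rotations, geometry, config.interp, config.supersample)
    resp, _ = responsibilities(patterns, slices, config, mask, rotations.weights)
    return rotations.quaternions[resp.modes()]


def rotation_error(
    estimated: np.ndarray,
    truth: np.ndarray,
    gauge_candidates: np.ndarray | None = None,
    align: bool = True,
    friedel: bool = True,
) -> float:
    """Mean angular distance (radians) after optimal global alignment.

    EMC solutions are defined up to one global rotation G (searched
    exhaustively over ``gauge_candidates``, by default the estimate/truth
    relative rotations) and, per pattern, up to the Friedel ambiguity: a
    Friedel-symmetric intensity gives the same slice at R and at R
    composed with a half-turn about the beam axis.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimate and truth sets must have the same size")
    c_beam = np.array([0.0, 0.0, 0.0, 1.0])  # half-turn about the beam axis

    def mean_err(gauge: np.ndarray | None) -> float:
        e = est if gauge is None else _quat_multiply(gauge[None, :], est)
        errs = quat_angle(e, tru)
        if friedel:
            tru_c = _quat_multiply(tru, c_beam[None, :])
            errs = np.minimum(errs, quat_angle(e, tru_c))
        return float(np.mean(np.minimum(errs, np.pi)))

    if not align:
        return mean_err(None)
    if gauge_candidates is None:
        # relative rotations truth * est^-1 are natural gauge candidates
        inv = est * np.array([1.0, -1.0, -1.0, -1.0])
        gauge_candidates = _quat_multiply(tru, inv)
    best = np.inf
    for g in np.asarray(gauge_candidates, dtype=float):
        g = g / np.linalg.norm(g)
        best = min(best, mean_err(g))
    return best
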