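"""Synthetic density maps, correlation coefficients, map alignment and FSC.

Maps are 3D scalar grids with an isotropic voxel size and an origin in
Angstrom; ``values[ix, iy, iz]`` sits at ``origin + voxel * (ix, iy, iz)``.
Model-derived maps place an isotropic Gaussian on every pseudo-atom.
Correlation coefficients use the about-mean (Pearson) convention inside the
mask.  MRC/CCP4 files are read and written through gemmi (mode 2, 32-bit
float), with voxel size and origin honoured on round trip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .model import Assembly, SubunitModel
from .rigid_geometry import Transform

#: default synthetic voxel size, Angstrom
DEFAULT_VOXEL = 2.0
#: default nominal resolution of synthetic maps, Angstrom
DEFAULT_RESOLUTION = 8.0
#: Gaussian sigma as a fraction of the nominal resolution
WIDTH_PER_RESOLUTION = 0.425


def default_width(resolution: float = DEFAULT_RESOLUTION) -> float:
    """Gaussian sigma (Angstrom) used to emulate a map at ``resolution``."""
    return WIDTH_PER_RESOLUTION * resolution


class GridMismatchError(ValueError):
    """Raised when two maps do not share one voxel grid."""


@dataclass
class DensityMap:
    """A 3D scalar grid with voxel size and origin in Angstrom."""

    values: np.ndarray
    voxel: float
    origin: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3D with at least 2 voxels per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.voxel - other.voxel) <= tol
                and np.allclose(self.origin, other.origin, atol=tol))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate vectors of the voxel centers."""
        return tuple(self.origin[i] + self.voxel * np.arange(self.shape[i])
                     for i in range(3))

    def center_of_mass(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        v = v - v.min()
        total = v.sum()
        if total <= 0:
            return self.origin + self.voxel * (np.array(self.shape) - 1) / 2.0
        idx = np.indices(self.shape)
        com_idx = np.array([(idx[i] * v).sum() / total for i in range(3)])
        return self.origin + self.voxel * com_idx

    def copy(self) -> "DensityMap":
        return dataclasses.replace(self, values=self.values.copy(),
                                   origin=self.origin.copy())


@dataclass
class FSCCurve:
    """Fourier shell correlation per resolution shell."""

    frequencies: np.ndarray    # shell centers, 1/Angstrom, strictly increasing
    correlations: np.ndarray   # in [-1, 1]

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")


def _model_points(model: Assembly | SubunitModel | np.ndarray) -> np.ndarray:
    if isinstance(model, Assembly):
        return model.all_points()
    if isinstance(model, SubunitModel):
        return model.points
    return np.asarray(model, dtype=float).reshape(-1, 3)


def make_grid(points: np.ndarray, voxel: float, pad: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Voxel-aligned grid (origin, shape) covering ``points`` plus ``pad``.

    The origin snaps to integer multiples of the voxel size so that a model
    translated by exactly one voxel produces the identical (shifted) grid.
    """
    lo = np.floor((points.min(axis=0) - pad) / voxel) * voxel
    hi = points.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel)) + 1 for i in range(3))
    return lo, shape


def rasterize(model: Assembly | SubunitModel | np.ndarray,
              voxel: float = DEFAULT_VOXEL,
              width: float | None = None,
              grid: tuple[np.ndarray, tuple[int, int, int]] | None = None) -> DensityMap:
    """Simulate a density map: one unit-weight Gaussian per pseudo-atom.

    ``width`` is the Gaussian sigma (default ``0.425 * 8 A``).  The grid pads
    the model bounding box by ``3 * width`` unless an explicit ``(origin,
    shape)`` grid is given (used to rasterize two models on one shared grid).
    The map integrates to the number of points within ~1 %.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if width is None:
        width = default_width()
    if width <= 0:
        raise ValueError("gaussian width must be positive")
    pts = _model_points(model)
    if len(pts) == 0:
        raise ValueError("cannot rasterize an empty model")
    if grid is None:
        origin, shape = make_grid(pts, voxel, 3.0 * width)
    else:
        origin, shape = np.asarray(grid[0], dtype=float), tuple(grid[1])
    values = np.zeros(shape, dtype=np.float64)
    half = int(np.ceil(4.0 * width / voxel))           # 4-sigma stamp
    norm = (2.0 * np.pi * width ** 2) ** -1.5
    axes_idx = [np.arange(s) for s in shape]
    for p in pts:
        ginds, gs = [], []
        for ax in range(3):
            centre = (p[ax] - origin[ax]) / voxel
            i0 = max(int(np.floor(centre)) - half, 0)
            i1 = min(int(np.ceil(centre)) + half, shape[ax] - 1)
            if i1 < i0:
                continue
            ii = axes_idx[ax][i0:i1 + 1]
            x = origin[ax] + voxel * ii - p[ax]
            ginds.append((i0, i1 + 1))
            gs.append(np.exp(-0.5 * (x / width) ** 2))
        if len(gs) != 3:
            continue
        block = norm * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        values[ginds[0][0]:ginds[0][1],
               ginds[1][0]:ginds[1][1],
               ginds[2][0]:ginds[2][1]] += block
    return DensityMap(values, voxel, origin, provenance="rasterized")


def correlation(a: DensityMap, b: DensityMap, mask: np.ndarray | None = None) -> float:
    """About-mean Pearson correlation between two maps over ``mask``."""
    if not a.same_grid(b):
        raise GridMismatchError("correlation requires maps on the same grid")
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise GridMismatchError("mask shape does not match the map grid")
        if not mask.any():
            raise ValueError("correlation mask is empty")
        va, vb = va[mask], vb[mask]
    else:
        va, vb = va.ravel(), vb.ravel()
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined: constant map inside mask")
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


def subunit_mask(density: DensityMap, subunit: SubunitModel | np.ndarray,
                 radius: float) -> np.ndarray:
    """Boolean grid of voxels whose centers lie within ``radius`` of the subunit."""
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    pts = _model_points(subunit)
    tree = cKDTree(pts)
    lo = pts.min(axis=0) - radius - density.voxel
    hi = pts.max(axis=0) + radius + density.voxel
    i0 = np.maximum(np.floor((lo - density.origin) / density.voxel), 0).astype(int)
    i1 = np.minimum(np.ceil((hi - density.origin) / density.voxel),
                    np.array(density.shape) - 1).astype(int)
    mask = np.zeros(density.shape, dtype=bool)
    if np.any(i1 < i0):
        raise ValueError("subunit mask is empty (subunit outside the grid)")
    ax = [density.origin[k] + density.voxel * np.arange(i0[k], i1[k] + 1) for k in range(3)]
    centers = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = tree.query(centers, k=1)
    sub = (d <= radius).reshape(i1[0] - i0[0] + 1, i1[1] - i0[1] + 1, i1[2] - i0[2] + 1)
    mask[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] = sub
    if not mask.any():
        raise ValueError("subunit mask is empty")
    return mask


# ---------------------------------------------------------------------------
# map alignment


def resample(moving: DensityMap, transform: Transform, like: DensityMap) -> np.ndarray:
    """Values of ``moving`` moved by ``transform``, sampled on ``like``'s grid.

    Trilinear interpolation; samples outside the moving grid take the moving
    map's mean (not zero) to avoid edge bias in correlations.
    """
    R, t = transform.rotation, transform.translation
    A = R.T * (like.voxel / moving.voxel)
    b = (R.T @ (like.origin - t) - moving.origin) / moving.voxel
    cval = float(np.asarray(moving.values, dtype=float).mean())
    return ndimage.affine_transform(
        np.asarray(moving.values, dtype=float), A, offset=b,
        output_shape=like.shape, order=1, mode="constant", cval=cval)


def _transform_cc(params: np.ndarray, base: Transform, moving: DensityMap,
                  fixed: DensityMap, pivot: np.ndarray) -> float:
    rv = params[:3]
    dt = params[3:]
    Rloc = Rotation.from_rotvec(rv).as_matrix()
    R = base.rotation @ Rloc
    # keep the pivot (moving center of mass) fixed under the local rotation
    t = base.translation + base.rotation @ (pivot - Rloc @ pivot) + dt
    vals = resample(moving, Transform(R, t), fixed)
    va = vals.ravel() - vals.mean()
    vb = np.asarray(fixed.values, dtype=float).ravel()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return -1.0
    return float(va @ vb / (na * nb))


def _downsample(density: DensityMap, factor: int) -> DensityMap:
    if factor <= 1:
        return density
    v = density.values
    s = [(dim // factor) * factor for dim in v.shape]
    v = v[:s[0], :s[1], :s[2]]
    v = v.reshape(s[0] // factor, factor, s[1] // factor, factor,
                  s[2] // factor, factor).mean(axis=(1, 3, 5))
    return DensityMap(v, density.voxel * factor, density.origin.copy(),
                      provenance=density.provenance)


#: number of coarse orientations for the rotation search
COARSE_ORIENTATIONS = 576
#: fixed seed of the deterministic coarse SO(3) sample
_COARSE_SEED = 20230417


def coarse_orientations(n: int = COARSE_ORIENTATIONS) -> np.ndarray:
    """Deterministic quasi-uniform sample of SO(3) (~30 degree spacing).

    The identity is always the first element, so maps that are already
    close to aligned refine from zero rotation.
    """
    sample = Rotation.random(n - 1,
                             random_state=np.random.RandomState(_COARSE_SEED))
    return np.concatenate([np.eye(3)[None], sample.as_matrix()])


def align_maps(moving: DensityMap, fixed: DensityMap,
               n_orientations: int = COARSE_ORIENTATIONS) -> tuple[Transform, float, bool]:
    """Rigid-body map superposition by correlation maximization.

    Coarse stage: ~600 quasi-uniform orientations, each scored on 4x
    downsampled maps with the translation set by center-of-mass matching.
    The best orientation seeds a derivative-free (Nelder-Mead) refinement of
    all 6 rigid parameters, first downsampled, then at full resolution.

    Returns ``(transform, cc, converged)``; for a symmetric fixed map any
    group-equivalent optimum is a valid result.
    """
    com_m = moving.center_of_mass()
    com_f = fixed.center_of_mass()
    ds = max(1, int(round(max(max(moving.shape), max(fixed.shape)) / 48)))
    small_m = _downsample(moving, ds)
    small_f = _downsample(fixed, ds)
    best_cc, best_R = -2.0, np.eye(3)
    zero6 = np.zeros(6)
    for R in coarse_orientations(n_orientations):
        t = com_f - R @ com_m
        cc = _transform_cc(zero6, Transform(R, t), small_m, small_f, com_m)
        # ties broken by smallest rotation angle
        if cc > best_cc + 1e-12 or (abs(cc - best_cc) <= 1e-12 and
                                    np.trace(R) > np.trace(best_R)):
            best_cc, best_R = cc, R
    base = Transform(best_R, com_f - best_R @ com_m)

    converged = True
    for mv, fx, iters in ((small_m, small_f, 400), (moving, fixed, 120)):
        res = minimize(lambda p: -_transform_cc(p, base, mv, fx, com_m), zero6,
                       method="Nelder-Mead",
                       options={"maxiter": iters, "xatol": 1e-4, "fatol": 1e-7,
                                "initial_simplex": _initial_simplex(mv.voxel)})
        converged = converged and bool(res.success)
        rv, dt = res.x[:3], res.x[3:]
        Rloc = Rotation.from_rotvec(rv).as_matrix()
        t = base.translation + base.rotation @ (com_m - Rloc @ com_m) + dt
        base = Transform(base.rotation @ Rloc, t)
    cc = _transform_cc(zero6, base, moving, fixed, com_m)
    return base, cc, converged


def _initial_simplex(voxel: float) -> np.ndarray:
    step = np.array([0.12, 0.12, 0.12, voxel, voxel, voxel])
    simplex = np.zeros((7, 6))
    for i in range(6):
        simplex[i + 1, i] = step[i]
    return simplex


# ---------------------------------------------------------------------------
# Fourier shell correlation


def fsc(a: DensityMap, b: DensityMap) -> FSCCurve:
    """FSC between two maps on the same grid, shells one Fourier voxel wide."""
    if not a.same_grid(b):
        raise GridMismatchError("fsc requires maps on the same grid")
    fa = np.fft.fftn(np.asarray(a.values, dtype=float))
    fb = np.fft.fftn(np.asarray(b.values, dtype=float))
    freqs = [np.fft.fftfreq(n, d=a.voxel) for n in a.shape]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    n_max = min(a.shape)
    shell_width = 1.0 / (n_max * a.voxel)
    shell = np.rint(radius / shell_width).astype(int)
    nyquist_shell = n_max // 2
    num = np.real(fa * np.conj(fb))
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    out_f, out_c = [], []
    for s in range(1, nyquist_shell + 1):
        sel = shell == s
        if not sel.any():
            continue
        denom = np.sqrt(pa[sel].sum() * pb[sel].sum())
        c = num[sel].sum() / denom if denom > 0 else 0.0
        out_f.append(s * shell_width)
        out_c.append(np.clip(c, -1.0, 1.0))
    return FSCCurve(np.array(out_f), np.array(out_c))


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float | None:
    """Resolution (Angstrom) at the first downward crossing of ``threshold``.

    Linear interpolation between shells; ``None`` means the curve never
    falls below the threshold before Nyquist ("beyond Nyquist").
    """
    f, c = curve.frequencies, curve.correlations
    for i in range(len(c) - 1):
        if c[i] >= threshold > c[i + 1]:
            frac = (c[i] - threshold) / (c[i] - c[i + 1])
            freq = f[i] + frac * (f[i + 1] - f[i])
            return float(1.0 / freq)
    if c[0] < threshold:
        return float(1.0 / f[0])
    return None


def low_pass_filter(density: DensityMap, resolution: float) -> DensityMap:
    """Sharp spherical low-pass at ``resolution`` Angstrom."""
    fa = np.fft.fftn(np.asarray(density.values, dtype=float))
    freqs = [np.fft.fftfreq(n, d=density.voxel) for n in density.shape]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    fa[radius > 1.0 / resolution] = 0.0
    return DensityMap(np.real(np.fft.ifftn(fa)), density.voxel,
                      density.origin.copy(), provenance="low-pass")


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (gemmi; mode 2 float32)


def write_mrc(density: DensityMap, path: str) -> None:
    """Write a map as MRC/CCP4 mode 2; voxel size and origin stored exactly."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(density.values, dtype=np.float32))
    nx, ny, nz = density.shape
    m.grid.unit_cell = gemmi.UnitCell(nx * density.voxel, ny * density.voxel,
                                      nz * density.voxel, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header(2, True)
    for k in range(3):                       # MRC2014 ORIGIN words 50..52
        m.set_header_float(50 + k, float(density.origin[k]))
    m.write_ccp4_map(str(path))


def read_mrc(path: str) -> DensityMap:
    """Read an MRC/CCP4 map written by :func:`write_mrc` (or compatible)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True)
    spacing = m.grid.spacing
    voxel = float(spacing[0])
    if max(abs(spacing[i] - voxel) for i in range(3)) > 1e-4:
        raise ValueError("only isotropic voxel sizes are supported")
    origin = np.array([m.header_float(50 + k) for k in range(3)])
    return DensityMap(values, voxel, origin, provenance=f"mrc:{path}")
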