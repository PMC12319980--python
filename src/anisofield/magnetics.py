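"""Current-induced magnetic flux density: the B_z component from volumetric
current densities (FFT fast path + direct-summation oracle) and from
line-current cable paths, plus stray-field correction of measured maps.

Only B_z is computed and reported: the MREIT measurement is sensitive solely
to the field component along the scanner's main axis (z). All B_z values are
in nT; current densities are in A/m^2 and grid spacing in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft

__all__ = [
    "MU0",
    "BzMap",
    "WirePath",
    "bz_from_j_fft",
    "bz_direct",
    "wire_bz",
    "stray_correct",
]

#: Vacuum permeability, T*m/A.
MU0 = 4e-7 * np.pi

_DIRECT_GUARD = 33**3  # largest grid allowed on the O(N*M) direct path


@dataclass
class BzMap:
    """B_z values (nT) on a grid or slice, with validity mask and provenance."""

    values: np.ndarray
    mask: np.ndarray = None
    provenance: str = "simulated"  # simulated | synthetic-measured | corrected

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, bool)
        self.mask = np.asarray(self.mask, bool)
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite B_z values inside the mask")


@dataclass
class WirePath:
    """Polyline cable path (points in mm) carrying a signed current in mA."""

    points: np.ndarray
    current_mA: float

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("wire path needs >= 2 finite 3D points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("wire path contains non-finite coordinates")

    @classmethod
    def from_csv(cls, path) -> "WirePath":
        arr = np.loadtxt(path, delimiter=",")
        return cls(arr[:, :3], float(arr[0, 3]))


def _voxel_coords_m(shape, spacing_mm, origin_mm=None):
    spacing = np.broadcast_to(np.asarray(spacing_mm, float), (3,))
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, float)
    axes = [
        (origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a]) * 1e-3
        for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij"), spacing * 1e-3


def bz_from_j_fft(J: np.ndarray, spacing_mm) -> BzMap:
    """B_z (nT) of a compactly supported current density via FFT convolution.

    B_z(r) = mu0/4pi * integral [J_x (y-y') - J_y (x-x')]/|r-r'|^3 dV',
    discretized at voxel centers with >=2x zero padding per axis and the
    singular self-voxel kernel term set to zero (its contribution vanishes by
    symmetry for piecewise-constant J). J_z does not enter B_z.
    """
    J = np.asarray(J, float)
    if J.ndim != 4 or J.shape[-1] != 3:
        raise ValueError("J must have shape (nx, ny, nz, 3)")
    shape = J.shape[:3]
    spacing = np.broadcast_to(np.asarray(spacing_mm, float), (3,)) * 1e-3
    dV = float(np.prod(spacing))

    # warn if current reaches the grid border (insufficient zero padding)
    jmag = np.linalg.norm(J, axis=-1)
    border = np.zeros(shape, bool)
    for a in range(3):
        sl = [slice(None)] * 3
        sl[a] = 0
        border[tuple(sl)] = True
        sl[a] = -1
        border[tuple(sl)] = True
    if jmag.max() > 0 and jmag[border].max() > 0.01 * jmag.max():
        warnings.warn("current density touches the grid border; "
                      "B_z may be inaccurate (insufficient support padding)")

    pad = tuple(2 * n for n in shape)
    # kernel of displacement u: G_k(u) = u_k / |u|^3, wrapped layout
    offs = []
    for a, n in enumerate(shape):
        idx = np.arange(pad[a])
        idx = np.where(idx < n, idx, idx - pad[a])
        offs.append(idx * spacing[a])
    ux, uy, _ = np.meshgrid(*offs, indexing="ij")
    r2 = ux**2 + uy**2 + np.meshgrid(*offs, indexing="ij")[2] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r3 = np.where(r2 > 0, r2 ** (-1.5), 0.0)
    Gx = ux * inv_r3
    Gy = uy * inv_r3

    fJx = fft.rfftn(J[..., 0], s=pad)
    fJy = fft.rfftn(J[..., 1], s=pad)
    conv = fft.irfftn(fJx * fft.rfftn(Gy), s=pad) - fft.irfftn(
        fJy * fft.rfftn(Gx), s=pad
    )
    bz = MU0 / (4 * np.pi) * dV * conv[: shape[0], : shape[1], : shape[2]]
    return BzMap(bz * 1e9, provenance="simulated")


def bz_direct(J: np.ndarray, spacing_mm, eval_points_m=None) -> BzMap:
    """Direct O(N*M) Biot-Savart summation; oracle for the FFT path.

    Guarded to small grids. ``eval_points_m`` defaults to all voxel centers.
    """
    J = np.asarray(J, float)
    shape = J.shape[:3]
    if np.prod(shape) > _DIRECT_GUARD:
        raise ValueError("grid too large for direct summation; use bz_from_j_fft")
    (x, y, z), spacing = _voxel_coords_m(shape, spacing_mm)
    src = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=-1)
    jx = J[..., 0].ravel()
    jy = J[..., 1].ravel()
    dV = float(np.prod(spacing))

    if eval_points_m is None:
        pts = src
        out_shape = shape
        self_exclude = True
    else:
        pts = np.atleast_2d(np.asarray(eval_points_m, float))
        out_shape = (len(pts),)
        self_exclude = False

    bz = np.empty(pts.shape[0])
    for i, p in enumerate(pts):
        d = p - src
        r2 = (d**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r3 = np.where(r2 > 0, r2 ** (-1.5), 0.0)
        if self_exclude:
            inv_r3[r2 == 0] = 0.0  # singular self-term
        bz[i] = ((jx * d[:, 1] - jy * d[:, 0]) * inv_r3).sum()
    bz = MU0 / (4 * np.pi) * dV * bz * 1e9
    return BzMap(bz.reshape(out_shape), provenance="simulated")


def wire_bz(path: WirePath, eval_points_mm) -> BzMap:
    """B_z (nT) of a polyline line current via the closed-form finite-segment
    Biot-Savart formula, summed over segments.

    Evaluation points closer than 1e-6 mm to any segment are flagged invalid
    (masked out) rather than returning a singular value.
    """
    pts = np.atleast_2d(np.asarray(eval_points_mm, float)) * 1e-3
    seg_a = path.points[:-1] * 1e-3
    seg_b = path.points[1:] * 1e-3
    I = path.current_mA * 1e-3
    bz = np.zeros(len(pts))
    valid = np.ones(len(pts), bool)
    for p1, p2 in zip(seg_a, seg_b):
        a = p1 - pts  # (m, 3)
        b = p2 - pts
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cross = np.cross(a, b)
        denom = na * nb * (na * nb + (a * b).sum(axis=1))
        # distance to the segment line for the singularity guard
        seg = p2 - p1
        seg_len = np.linalg.norm(seg)
        dist_line = np.linalg.norm(cross, axis=1) / max(seg_len, 1e-300)
        t = -(a @ seg) / max(seg_len**2, 1e-300)
        on_span = (t >= 0) & (t <= 1)
        too_close = on_span & (dist_line < 1e-9) | (na < 1e-9) | (nb < 1e-9)
        valid &= ~too_close
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = cross[:, 2] * (na + nb) / denom
        contrib[~np.isfinite(contrib)] = 0.0
        bz += contrib
    bz = MU0 / (4 * np.pi) * I * bz * 1e9
    bz[~valid] = 0.0
    return BzMap(bz, mask=valid, provenance="simulated")


def stray_correct(bz_measured: BzMap, path: WirePath,
                  eval_points_mm) -> BzMap:
    """Subtract the cable stray field from a measured B_z map.

    Not idempotent: applying it twice subtracts the wire field twice.
    """
    wire = wire_bz(path, eval_points_mm)
    vals = bz_measured.values - wire.values.reshape(bz_measured.values.shape)
    return BzMap(vals, bz_measured.mask & wire.mask.reshape(bz_measured.mask.shape),
                 provenance="corrected")
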