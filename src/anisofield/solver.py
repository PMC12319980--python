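"""Quasi-static anisotropic current-flow solver on the voxel grid.

Solves div(sigma grad phi) = 0 with node-based trilinear hexahedral finite
elements, one full 3x3 conductivity tensor per voxel/element. Electrodes are
Dirichlet patches held at +/-0.5 V; after the solve, all fields are rescaled
so that the total current through the anode equals the montage's injected
current (the tES contract: fields are reported for a set current, which also
makes the current density invariant to a global conductivity scaling).

The non-conducting exterior (label 0) is simply excluded from assembly, which
imposes the natural no-flux boundary condition on the outer surface.

Units: spacing is given in mm and converted to metres internally, so phi is
in V, E in V/m and J in A/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, splu

from .grids import LabeledVolume, TensorField
from .phantoms import Montage

__all__ = [
    "SolverConfig",
    "FieldSolution",
    "solve_potential",
    "compute_fields",
    "extract_masked_slice",
    "mid_gm_shell",
]

_ELEMENT_NODE_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
     (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
)

# Jacobi-CG beats SuperLU at every grid size tried here; "auto" always picks
# CG and sparse LU remains available on request
_DIRECT_LIMIT = 0


@dataclass
class SolverConfig:
    rtol: float = 1e-8
    maxiter: int = 20_000
    method: str = "auto"  # auto | direct | cg

    def __post_init__(self):
        if not (0 < self.rtol <= 1e-3):
            raise ValueError("solver relative tolerance must be in (0, 1e-3]")


@dataclass
class FieldSolution:
    """Potential (node grid, V), E-field and current density (per voxel)."""

    phi: np.ndarray          # (nx+1, ny+1, nz+1), NaN at non-conducting nodes
    E: np.ndarray            # (nx, ny, nz, 3) V/m
    J: np.ndarray            # (nx, ny, nz, 3) A/m^2
    montage: Montage
    current_mA: float
    residual: float
    _diag: dict = field(default_factory=dict, repr=False)

    def interior_divergence(self) -> float:
        """Max nodal current imbalance at free interior nodes, as a fraction
        of the injected current — the discrete statement of div(J) = 0."""
        K = self._diag["K"]
        phi = self._diag["phi_active"]
        free = self._diag["free"]
        r = (K @ phi)[free]
        return float(np.abs(r).max() / (self.current_mA * 1e-3))

    def patch_currents(self) -> tuple[float, float]:
        """Currents (A) through anode and cathode patches (should be +/-I)."""
        K = self._diag["K"]
        phi = self._diag["phi_active"]
        r = K @ phi
        return (
            float(r[self._diag["anode"]].sum()),
            float(r[self._diag["cathode"]].sum()),
        )


def _element_component_matrices(spacing_m: np.ndarray) -> np.ndarray:
    """G[k,l] (8x8): integral of dN_a/dx_k dN_b/dx_l over one hexahedron.

    2-point Gauss quadrature per axis, exact for trilinear elements.
    """
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([(sx * g, sy * g, sz * g)
                    for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    signs = 2.0 * _ELEMENT_NODE_OFFSETS - 1.0  # (8,3) in {-1,1}
    detJ = np.prod(spacing_m) / 8.0
    G = np.zeros((3, 3, 8, 8))
    for xi in pts:
        grad = np.empty((8, 3))
        for a in range(8):
            sa = signs[a]
            grad[a, 0] = sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2]) / 8.0
            grad[a, 1] = sa[1] * (1 + sa[0] * xi[0]) * (1 + sa[2] * xi[2]) / 8.0
            grad[a, 2] = sa[2] * (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1]) / 8.0
        grad *= 2.0 / spacing_m  # reference -> physical derivatives
        G += np.einsum("ak,bl->klab", grad, grad) * detJ
    return G


def _check_connected(labels: LabeledVolume, montage: Montage):
    cond, _ = ndimage.label(labels.labels > 0)
    va = montage.patch_a[0, :3]
    vb = montage.patch_b[0, :3]
    if cond[tuple(va)] != cond[tuple(vb)]:
        raise ValueError("electrode patches are not connected by conducting tissue")


def solve_potential(sigma: TensorField, labels: LabeledVolume,
                    montage: Montage, config: SolverConfig | None = None,
                    check_spd: bool = True) -> FieldSolution:
    """Solve the current-flow problem for one montage.

    Returns fields normalized so the surface-integrated anode current equals
    ``montage.current_mA``.
    """
    config = config or SolverConfig()
    cond = labels.labels > 0
    if check_spd:
        sigma.require_spd(cond)
    _check_connected(labels, montage)

    nx, ny, nz = labels.shape
    spacing_m = labels.spacing * 1e-3
    G = _element_component_matrices(spacing_m)

    elems = np.argwhere(cond)
    node_shape = (nx + 1, ny + 1, nz + 1)
    # global node ids of the 8 corners of each conducting element
    corner = elems[:, None, :] + _ELEMENT_NODE_OFFSETS[None, :, :]
    gid = np.ravel_multi_index(
        (corner[..., 0], corner[..., 1], corner[..., 2]), node_shape
    )  # (ne, 8)

    sig = sigma.tensors[cond]  # (ne, 3, 3)
    Ke = np.einsum("ekl,klab->eab", sig, G)

    active = np.unique(gid)
    comp = np.full(np.prod(node_shape), -1, np.int64)
    comp[active] = np.arange(active.size)
    rows = comp[np.repeat(gid, 8, axis=1).ravel()]
    cols = comp[np.tile(gid, (1, 8)).ravel()]
    K = sparse.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(active.size, active.size)
    ).tocsr()

    def node_ids(which):
        n = montage.patch_nodes(which)
        ids = comp[np.ravel_multi_index((n[:, 0], n[:, 1], n[:, 2]), node_shape)]
        if np.any(ids < 0):
            raise ValueError("electrode patch touches non-conducting nodes")
        return ids

    anode, cathode = node_ids("a"), node_ids("b")
    phi = np.zeros(active.size)
    phi[anode] = 0.5
    phi[cathode] = -0.5
    constrained = np.zeros(active.size, bool)
    constrained[anode] = True
    constrained[cathode] = True
    free = ~constrained

    Kff = K[free][:, free]
    rhs = -(K[free][:, constrained] @ phi[constrained])
    nfree = int(free.sum())
    method = config.method
    if method == "auto":
        method = "direct" if nfree <= _DIRECT_LIMIT else "cg"
    if method == "direct":
        phi_f = splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A").solve(rhs)
        residual = float(
            np.linalg.norm(Kff @ phi_f - rhs) / max(np.linalg.norm(rhs), 1e-300)
        )
    else:
        M = sparse.diags(1.0 / Kff.diagonal())
        phi_f, info = cg(Kff, rhs, rtol=config.rtol, maxiter=config.maxiter, M=M)
        residual = float(
            np.linalg.norm(Kff @ phi_f - rhs) / max(np.linalg.norm(rhs), 1e-300)
        )
        if info != 0 or residual > 10 * config.rtol:
            raise RuntimeError(
                f"iterative solve did not converge (info={info}, "
                f"relative residual={residual:.2e})"
            )
    phi[free] = phi_f

    i_raw = float((K @ phi)[anode].sum())
    if abs(i_raw) < 1e-300:
        raise ValueError("no current flows between the electrode patches")
    scale = montage.current_mA * 1e-3 / i_raw
    phi *= scale

    phi_grid = np.full(node_shape, np.nan)
    phi_grid.ravel()[active] = phi
    E, J = compute_fields(phi_grid, sigma, labels)
    return FieldSolution(
        phi_grid, E, J, montage, montage.current_mA, residual,
        _diag={"K": K, "phi_active": phi, "free": free,
               "anode": anode, "cathode": cathode},
    )


def compute_fields(phi: np.ndarray, sigma: TensorField,
                   labels: LabeledVolume) -> tuple[np.ndarray, np.ndarray]:
    """Element-center E = -grad(phi) (trilinear gradient) and J = sigma E."""
    spacing_m = labels.spacing * 1e-3
    P = np.nan_to_num(phi, nan=0.0)
    grad = np.empty(labels.shape + (3,))

    def face_mean(arr, axis):
        # mean over the 4 nodes of each element face normal to `axis`
        others = [a for a in range(3) if a != axis]
        s = arr
        for a in others:
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[a] = slice(None, -1)
            hi[a] = slice(1, None)
            s = 0.5 * (s[tuple(lo)] + s[tuple(hi)])
        return s

    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = P[tuple(hi)] - P[tuple(lo)]
        grad[..., axis] = face_mean(diff, axis) / spacing_m[axis]

    cond = labels.labels > 0
    E = np.where(cond[..., None], -grad, 0.0)
    J = np.einsum("...ij,...j->...i", sigma.tensors, E)
    J[~cond] = 0.0
    return E, J


def extract_masked_slice(fieldvals: np.ndarray, labels: LabeledVolume,
                         axis: int, index: int,
                         tissues=("gm", "wm", "csf")):
    """2D slice of a voxel field restricted to the given tissue set.

    Returns (values, mask); values outside the mask are left in place but the
    mask flags them invalid and all metrics must honor it.
    """
    if not (0 <= index < labels.shape[axis]):
        raise ValueError("slice index outside the grid")
    sl = [slice(None)] * 3
    sl[axis] = index
    sl = tuple(sl)
    mask = labels.mask(*tissues)[sl]
    if not mask.any():
        raise ValueError("slice contains no voxels of the requested tissues")
    return np.asarray(fieldvals)[sl], mask


def mid_gm_shell(labels: LabeledVolume) -> np.ndarray:
    """Boolean mask of GM voxels halfway between CSF and WM.

    Voxel surrogate of the middle gray-matter surface: GM voxels whose
    Euclidean distance to CSF differs from the distance to WM by at most one
    voxel. Falls back to all GM voxels (with a warning) if GM is too thin.
    """
    import warnings

    gm = labels.mask("gm")
    if not gm.any():
        raise ValueError("phantom has no GM")
    d_csf = ndimage.distance_transform_edt(~labels.mask("csf"),
                                           sampling=labels.spacing)
    d_wm = ndimage.distance_transform_edt(~labels.mask("wm"),
                                          sampling=labels.spacing)
    shell = gm & (np.abs(d_csf - d_wm) <= labels.spacing.max())
    if not shell.any():
        warnings.warn("GM too thin for a mid-shell; using all GM voxels")
        return gm
    return shell
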