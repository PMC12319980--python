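"""Synthetic phantoms: layered head-like volumes, a z-invariant cylinder
phantom with anisotropic inclusions, diffusion-tensor synthesis, electrode
montages, and noisy synthetic B_z measurements.

These generators stand in for the MR-derived inputs of the real pipeline
(segmented head models, DTI tensor fits, MREIT acquisitions) so that every
downstream stage can be exercised without any imaging data. Geometry is
idealized (ellipsoidal shells, cylinders); the physics downstream is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LabeledVolume, TensorField

__all__ = [
    "Montage",
    "NoiseSpec",
    "make_layered_phantom",
    "default_head_phantom",
    "make_cylinder_phantom",
    "cylinder_montages",
    "synth_diffusion_tensors",
    "make_montage",
    "make_strip_montage",
    "make_noisy_bz",
    "surface_faces",
]

# A boundary face is (i, j, k, axis, side): the face of voxel (i,j,k) on the
# negative (side=0) or positive (side=1) end of `axis`.


@dataclass
class Montage:
    """Two electrode patches on the outer tissue boundary plus the injected
    current (mA, baseline-to-peak). Patch A is the anode (+I), B the cathode."""

    patch_a: np.ndarray  # (n, 5) int faces
    patch_b: np.ndarray
    current_mA: float = 1.0
    name: str = ""

    def __post_init__(self):
        self.patch_a = np.atleast_2d(np.asarray(self.patch_a, int))
        self.patch_b = np.atleast_2d(np.asarray(self.patch_b, int))
        if len(self.patch_a) == 0 or len(self.patch_b) == 0:
            raise ValueError("electrode patches must be non-empty")
        a = {tuple(f) for f in self.patch_a}
        b = {tuple(f) for f in self.patch_b}
        if a & b:
            raise ValueError("electrode patches overlap")

    def patch_nodes(self, which: str) -> np.ndarray:
        """Unique node-grid indices (n, 3) of the corners of a patch's faces."""
        faces = self.patch_a if which == "a" else self.patch_b
        nodes = []
        for i, j, k, axis, side in faces:
            base = np.array([i, j, k])
            base[axis] += side
            for u in (0, 1):
                for v in (0, 1):
                    n = base.copy()
                    ax_u, ax_v = [a for a in range(3) if a != axis]
                    n[ax_u] += u
                    n[ax_v] += v
                    n[axis] = base[axis]
                    nodes.append(tuple(n))
        return np.array(sorted(set(nodes)), int)


@dataclass
class NoiseSpec:
    """Gaussian measurement-noise model for synthetic B_z maps (std in nT)."""

    std_nT: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.std_nT < 0:
            raise ValueError("noise std must be >= 0")


def make_layered_phantom(shape, spacing, shell_radii: dict, tissue_order=None,
                         origin=None) -> LabeledVolume:
    """Concentric ellipsoidal-shell phantom, labeled outside-in.

    Parameters
    ----------
    shape : tuple of 3 ints
    spacing : float or 3-vector, mm
    shell_radii : dict
        tissue name -> semi-axis radius (scalar for a sphere or 3-vector),
        in mm, strictly decreasing from the outermost tissue inward. The last
        entry is a filled ball, the others shells.
    tissue_order : list of str, optional
        Order outermost -> innermost; defaults to dict insertion order.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    order = list(tissue_order) if tissue_order is not None else list(shell_radii)
    radii = [np.broadcast_to(np.asarray(shell_radii[t], float), (3,)) for t in order]

    for outer, inner, t_out, t_in in zip(radii, radii[1:], order, order[1:]):
        if not np.all(outer > inner):
            raise ValueError(
                f"shell radii must strictly decrease inward ({t_out} -> {t_in})"
            )
        if np.any(outer - inner < spacing):
            raise ValueError(
                f"shell {t_in!r} is thinner than one voxel "
                f"(thickness {tuple(outer - inner)} mm at spacing {tuple(spacing)} mm)"
            )
    extent = spacing * np.asarray(shape)
    if np.any(2 * radii[0] >= extent):
        raise ValueError("outermost shell does not fit inside the grid")

    if origin is None:
        origin = -0.5 * extent  # grid centered on the world origin
    vol = LabeledVolume(
        np.zeros(shape, np.int16), spacing, origin,
        tissues={t: i + 1 for i, t in enumerate(order)},
    )
    x, y, z = vol.voxel_centers()
    center = origin + 0.5 * extent
    labels = vol.labels
    for code, (t, r) in enumerate(zip(order, radii), start=1):
        inside = (
            ((x - center[0]) / r[0]) ** 2
            + ((y - center[1]) / r[1]) ** 2
            + ((z - center[2]) / r[2]) ** 2
        ) <= 1.0
        labels[inside] = code
    return vol


#: Default head-like phantom shell semi-axes (mm), outside-in.
HEAD_RADII = {
    "scalp": 60.0,
    "compact_bone": 54.0,
    "spongy_bone": 50.0,
    "csf": 44.0,
    "gm": 38.0,
    "wm": 30.0,
}


def default_head_phantom(shape=(64, 64, 64), spacing=2.0,
                         include_spongy=True) -> LabeledVolume:
    """Spherical 5/6-compartment head phantom (scalp, skull, CSF, GM, WM).

    The physical radii are fixed (outer radius 60 mm); `shape`/`spacing`
    set the resolution. Eyes, blood and muscle compartments of full head
    models are omitted: they carry no uncertainty prior and no anisotropy.
    """
    radii = dict(HEAD_RADII)
    if not include_spongy:
        del radii["spongy_bone"]
    return make_layered_phantom(shape, spacing, radii)


def synth_diffusion_tensors(
    labels: LabeledVolume,
    wm_fiber_model: dict | None = None,
    mean_diffusivities: dict | None = None,
    wm_anisotropy_ratio: float = 9.0,
    gm_anisotropy_ratio: float = 1.1,
) -> TensorField:
    """Synthesize a diffusion-tensor field (mm^2/s) on a labeled phantom.

    WM tensors are prolate with eigenvalue ratio ``wm_anisotropy_ratio``
    (largest eigenvalue along the fiber direction field); GM tensors are
    near-isotropic (ratio ``gm_anisotropy_ratio``, radially oriented); all
    other tissues are isotropic. At every voxel the geometric mean of the
    eigenvalues equals the requested per-tissue mean diffusivity exactly.

    ``wm_fiber_model``: ``{"kind": "uniform", "direction": (x,y,z)}`` or
    ``{"kind": "circumferential"}`` (tangential loops around the z axis).
    """
    if wm_anisotropy_ratio < 1 or gm_anisotropy_ratio < 1:
        raise ValueError("anisotropy ratios must be >= 1")
    wm_fiber_model = wm_fiber_model or {"kind": "circumferential"}
    md = dict(DEFAULT_MEAN_DIFFUSIVITY)
    if mean_diffusivities:
        md.update(mean_diffusivities)
    present = [t for t, c in labels.tissues.items() if (labels.labels == c).any()]
    missing = [t for t in present if t not in md]
    if missing:
        raise ValueError(f"no mean diffusivity given for tissues {missing}")
    if any(md[t] <= 0 for t in present):
        raise ValueError("mean diffusivities must be > 0")

    shape = labels.shape
    tensors = np.zeros(shape + (3, 3), float)
    mask = labels.labels > 0
    eye = np.eye(3)
    for t in present:
        tmask = labels.mask(t)
        if t == "wm":
            dirs = _fiber_directions(labels, tmask, wm_fiber_model)
            tensors[tmask] = _prolate_tensors(dirs, md[t], wm_anisotropy_ratio)
        elif t == "gm":
            dirs = _fiber_directions(labels, tmask, {"kind": "radial"})
            tensors[tmask] = _prolate_tensors(dirs, md[t], gm_anisotropy_ratio)
        else:
            tensors[tmask] = md[t] * eye
    return TensorField(tensors, mask, units="mm^2/s")


#: Representative mean diffusivities (mm^2/s) of head tissues.
DEFAULT_MEAN_DIFFUSIVITY = {
    "wm": 0.7e-3,
    "gm": 0.8e-3,
    "csf": 3.0e-3,
    "scalp": 1.0e-3,
    "compact_bone": 0.3e-3,
    "spongy_bone": 0.5e-3,
}


def _prolate_tensors(dirs: np.ndarray, geomean: float, ratio: float) -> np.ndarray:
    """Prolate tensors with lambda1:lambda2=ratio, lambda2=lambda3, principal
    axis along `dirs`, and eigenvalue geometric mean = `geomean` exactly."""
    lam_perp = geomean * ratio ** (-1.0 / 3.0)
    lam_par = geomean * ratio ** (2.0 / 3.0)
    outer = np.einsum("...i,...j->...ij", dirs, dirs)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * outer


def _fiber_directions(labels: LabeledVolume, tmask: np.ndarray, model: dict):
    kind = model.get("kind", "uniform")
    if kind == "uniform":
        v = np.asarray(model["direction"], float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("fiber direction field contains a zero-norm vector")
        return np.broadcast_to(v / norm, (int(tmask.sum()), 3)).copy()
    x, y, z = labels.voxel_centers()
    center = labels.origin + 0.5 * labels.spacing * np.asarray(labels.shape)
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    if kind == "circumferential":
        vecs = np.stack([-dy[tmask], dx[tmask], np.zeros(int(tmask.sum()))], axis=-1)
        fallback = np.array([1.0, 0.0, 0.0])
    elif kind == "radial":
        vecs = np.stack([dx[tmask], dy[tmask], dz[tmask]], axis=-1)
        fallback = np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError(f"unknown fiber model kind {kind!r}")
    norms = np.linalg.norm(vecs, axis=-1, keepdims=True)
    small = norms[:, 0] < 1e-9
    vecs[small] = fallback
    norms[small] = 1.0
    return vecs / norms


def surface_faces(labels: LabeledVolume) -> np.ndarray:
    """All outer boundary faces of the conducting region (label > 0)."""
    lab = labels.labels > 0
    faces = []
    for axis in range(3):
        for side in (0, 1):
            shifted = np.zeros_like(lab)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if side == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            shifted[tuple(dst)] = lab[tuple(src)]
            boundary = lab & ~shifted
            for i, j, k in np.argwhere(boundary):
                faces.append((i, j, k, axis, side))
    return np.array(faces, int)


def _face_centers(labels: LabeledVolume, faces: np.ndarray) -> np.ndarray:
    centers = labels.origin + (faces[:, :3] + 0.5) * labels.spacing
    offset = (faces[:, 4] - 0.5) * labels.spacing[faces[:, 3]]
    centers[np.arange(len(faces)), faces[:, 3]] += offset
    return centers


def make_montage(labels: LabeledVolume, center_a, center_b, diameter=35.0,
                 current_mA=1.0, name="", surface_tol=None) -> Montage:
    """Circular electrode patches on the phantom surface.

    Each patch consists of the outer boundary faces within ``diameter/2`` of
    the requested center, after projecting the center onto the nearest
    surface face. Current is +I at patch A (anode), -I at patch B.
    """
    if diameter < 2 * float(np.min(labels.spacing)):
        raise ValueError("electrode diameter must span at least two voxels")
    faces = surface_faces(labels)
    centers = _face_centers(labels, faces)
    if surface_tol is None:
        surface_tol = diameter
    patches = []
    for c in (np.asarray(center_a, float), np.asarray(center_b, float)):
        d = np.linalg.norm(centers - c, axis=1)
        if d.min() > surface_tol:
            raise ValueError(
                f"electrode center {tuple(c)} is {d.min():.1f} mm from the "
                "surface, beyond tolerance"
            )
        proj = centers[np.argmin(d)]
        sel = np.linalg.norm(centers - proj, axis=1) <= diameter / 2
        patches.append(faces[sel])
    return Montage(patches[0], patches[1], current_mA, name)


def make_strip_montage(labels: LabeledVolume, angle_a_deg, angle_b_deg,
                       width_deg=40.0, current_mA=1.0, name="") -> Montage:
    """Full-height strip electrodes on a lateral (cylindrical) surface.

    Strips span the whole z extent so the injected current stays purely
    transversal on z-invariant phantoms. Angles are measured in the xy plane
    around the phantom axis.
    """
    faces = surface_faces(labels)
    lateral = faces[faces[:, 3] != 2]  # exclude top/bottom caps
    centers = _face_centers(labels, lateral)
    axis = labels.origin + 0.5 * labels.spacing * np.asarray(labels.shape)
    ang = np.degrees(np.arctan2(centers[:, 1] - axis[1], centers[:, 0] - axis[0]))
    patches = []
    for a0 in (angle_a_deg, angle_b_deg):
        diff = (ang - a0 + 180.0) % 360.0 - 180.0
        patches.append(lateral[np.abs(diff) <= width_deg / 2])
    return Montage(patches[0], patches[1], current_mA, name)


def make_cylinder_phantom(
    shape=(48, 48, 16),
    spacing=1.0,
    background_radius=20.0,
    inclusion_radius=4.5,
    inclusion_offset=10.0,
    background_md=1.0e-3,
    inclusion_iso_md=2.0e-3,
    inclusion_ratio=5.0,
    inclusion_md=1.0e-3,
    smoothing_fwhm=2.0,
) -> tuple[LabeledVolume, TensorField]:
    """z-invariant validation phantom: an isotropic background cylinder holding
    one isotropic inclusion and three anisotropic inclusions whose principal
    diffusion directions are x-, y-, and 45deg-aligned.

    Paired lateral strip electrodes (see :func:`cylinder_montages`) inject
    predominantly horizontal currents, the regime in which transversal
    current-density reconstruction from B_z is well posed.

    The tensor field is smoothed with a small Gaussian (``smoothing_fwhm``
    mm) inside the cylinder, emulating the finite resolution of measured
    diffusion tensors and avoiding step discontinuities in the simulated
    current densities. Set to 0 for hard inclusion boundaries. Smoothing
    blends only collinear or isotropic neighbors here, so inclusion
    principal directions and the isotropy of the isotropic regions are
    preserved exactly; z-invariance is unaffected.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    extent = spacing * np.asarray(shape)
    if 2 * background_radius >= min(extent[0], extent[1]):
        raise ValueError("background cylinder does not fit inside the grid")
    if inclusion_offset + inclusion_radius > background_radius:
        raise ValueError("inclusions extend outside the background cylinder")
    if inclusion_radius * 2 > inclusion_offset * np.sqrt(2):
        raise ValueError("inclusions overlap")

    origin = -0.5 * extent
    tissues = {
        "background": 1,
        "iso_inclusion": 2,
        "aniso_x": 3,
        "aniso_y": 4,
        "aniso_45": 5,
    }
    vol = LabeledVolume(np.zeros(shape, np.int16), spacing, origin, tissues)
    x, y, _ = vol.voxel_centers()
    r2 = x**2 + y**2
    lab = vol.labels
    lab[r2 <= background_radius**2] = 1
    offsets = {
        "iso_inclusion": (inclusion_offset, 0.0),
        "aniso_x": (-inclusion_offset, 0.0),
        "aniso_y": (0.0, inclusion_offset),
        "aniso_45": (0.0, -inclusion_offset),
    }
    for t, (cx, cy) in offsets.items():
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= inclusion_radius**2
        lab[inside] = tissues[t]

    tensors = np.zeros(shape + (3, 3), float)
    tensors[lab == 1] = background_md * np.eye(3)
    tensors[lab == 2] = inclusion_iso_md * np.eye(3)
    s2 = np.sqrt(0.5)
    principal = {
        "aniso_x": np.array([1.0, 0.0, 0.0]),
        "aniso_y": np.array([0.0, 1.0, 0.0]),
        "aniso_45": np.array([s2, s2, 0.0]),
    }
    for t, v in principal.items():
        tmask = lab == tissues[t]
        n = int(tmask.sum())
        dirs = np.broadcast_to(v, (n, 3))
        tensors[tmask] = _prolate_tensors(dirs, inclusion_md, inclusion_ratio)
    if smoothing_fwhm > 0:
        from .grids import smooth_tensor_components

        tensors = smooth_tensor_components(tensors, lab > 0, smoothing_fwhm,
                                           spacing)
    return vol, TensorField(tensors, lab > 0, units="mm^2/s")


def cylinder_montages(labels: LabeledVolume, current_mA=1.0,
                      width_deg=40.0) -> list[Montage]:
    """The two orthogonal lateral electrode pairs of the cylinder phantom."""
    return [
        make_strip_montage(labels, 0.0, 180.0, width_deg, current_mA, name="x-pair"),
        make_strip_montage(labels, 90.0, -90.0, width_deg, current_mA, name="y-pair"),
    ]


def make_noisy_bz(bz_true: np.ndarray, noise: NoiseSpec,
                  stray: np.ndarray | None = None) -> np.ndarray:
    """Synthetic B_z measurement: truth + optional cable stray field + iid
    Gaussian noise (nT). Reproducible under a fixed seed."""
    bz_true = np.asarray(bz_true, float)
    out = bz_true.copy()
    if stray is not None:
        stray = np.asarray(stray, float)
        if stray.shape != bz_true.shape:
            raise ValueError("stray-field shape does not match B_z map")
        out = out + stray
    if noise.std_nT > 0:
        rng = np.random.default_rng(noise.seed)
        out = out + rng.normal(0.0, noise.std_nT, size=bz_true.shape)
    return out
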