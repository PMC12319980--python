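"""Core voxel-grid containers: labeled tissue volumes and symmetric tensor fields.

All volumes live on an axis-aligned structured grid. World coordinates are in
millimetres; the voxel with index ``(i, j, k)`` has its center at
``origin + (index + 0.5) * spacing``. The z axis is the scanner B0 axis, which
fixes the meaning of the measurable magnetic-field component B_z downstream.

Tensor fields store the full symmetric 3x3 matrix per voxel. On disk they are
exchanged as 4D NIfTI volumes with six component maps in the order
xx, yy, zz, xy, xz, yz (the upper triangle), the usual convention for
diffusion-tensor images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "TensorField",
    "tensor6_to_full",
    "full_to_tensor6",
    "eigenvalues_sym3",
    "geometric_mean_eigenvalues",
    "fractional_anisotropy",
    "spd_project",
    "smooth_tensor_components",
]

#: Upper-triangle component order used for 6-component tensor I/O.
TENSOR6_ORDER = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass
class LabeledVolume:
    """3D integer tissue-label grid with voxel spacing and world origin.

    Label 0 is non-conducting background (air); every other label must appear
    in ``tissues`` (name -> label code).
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    tissues: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, float)
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.tissues.values())
        if self.tissues and not present <= declared:
            raise ValueError(
                f"labels {sorted(present - declared)} not in the tissue dictionary"
            )

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the voxels carrying any of the named tissues."""
        codes = [self.tissues[n] for n in names]
        return np.isin(self.labels, codes)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinate arrays (broadcastable) of all voxel centers."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def affine(self) -> np.ndarray:
        aff = np.diag(np.append(self.spacing, 1.0))
        aff[:3, 3] = self.origin + 0.5 * self.spacing
        return aff

    def to_nifti(self, path):
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine()), path)

    @classmethod
    def from_nifti(cls, path, tissues=None) -> "LabeledVolume":
        img = nib.load(path)
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3] - 0.5 * spacing
        return cls(np.asarray(img.dataobj).astype(int), spacing, origin, tissues or {})


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor field (diffusion mm^2/s or conductivity S/m)."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    mask: np.ndarray = None  # validity mask; tensors outside are ignored
    units: str = ""

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, float)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:-2], bool)
        self.mask = np.asarray(self.mask, bool)

    @property
    def shape(self):
        return self.tensors.shape[:-2]

    def symmetrize(self) -> "TensorField":
        t = 0.5 * (self.tensors + np.swapaxes(self.tensors, -1, -2))
        return TensorField(t, self.mask, self.units)

    def is_spd(self, where=None) -> np.ndarray:
        """Boolean map: all eigenvalues strictly positive (on mask by default)."""
        where = self.mask if where is None else where
        ok = np.zeros(self.shape, bool)
        if where.any():
            ev = eigenvalues_sym3(self.tensors[where])
            ok[where] = ev.min(axis=-1) > 0
        return ok

    def require_spd(self, where=None):
        where = self.mask if where is None else where
        bad = where & ~self.is_spd(where)
        if bad.any():
            idx = np.argwhere(bad)
            first = tuple(int(v) for v in idx[0])
            raise ValueError(
                f"{int(bad.sum())} non-SPD tensors inside mask; first at voxel {first}"
            )

    def to_nifti(self, path, volume: LabeledVolume):
        comp = full_to_tensor6(self.tensors)
        nib.save(nib.Nifti1Image(comp.astype(np.float32), volume.affine()), path)

    @classmethod
    def from_nifti(cls, path, mask=None, units="") -> "TensorField":
        comp = np.asarray(nib.load(path).dataobj)
        if comp.ndim != 4 or comp.shape[-1] != 6:
            raise ValueError("expected a 4D NIfTI with 6 tensor components")
        return cls(tensor6_to_full(comp), mask, units)


def tensor6_to_full(comp: np.ndarray) -> np.ndarray:
    """Expand (..., 6) upper-triangle components (xx,yy,zz,xy,xz,yz) to (..., 3, 3)."""
    out = np.zeros(comp.shape[:-1] + (3, 3), float)
    for c, (i, j) in enumerate(TENSOR6_ORDER):
        out[..., i, j] = comp[..., c]
        out[..., j, i] = comp[..., c]
    return out


def full_to_tensor6(full: np.ndarray) -> np.ndarray:
    out = np.empty(full.shape[:-2] + (6,), float)
    for c, (i, j) in enumerate(TENSOR6_ORDER):
        out[..., c] = full[..., i, j]
    return out


def eigenvalues_sym3(t: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a stack of symmetric 3x3 matrices."""
    return np.linalg.eigvalsh(t)


def geometric_mean_eigenvalues(t: np.ndarray) -> np.ndarray:
    """Per-voxel geometric mean of the three eigenvalues, i.e. det(T)^(1/3).

    Valid only for SPD tensors, where det > 0.
    """
    det = np.linalg.det(t)
    return np.cbrt(det)


def fractional_anisotropy(t: np.ndarray) -> np.ndarray:
    """FA of each tensor: sqrt(3/2)*||lambda - mean||/||lambda||; 0 for isotropic."""
    ev = eigenvalues_sym3(t)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - mean) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


#: FWHM of a Gaussian in units of its standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_tensor_components(tensors: np.ndarray, mask: np.ndarray,
                             fwhm_mm: float, spacing) -> np.ndarray:
    """Component-wise Gaussian smoothing of a tensor field inside a mask.

    The kernel is renormalized at the mask edge (smoothing of masked
    components divided by the smoothed mask), so values outside the mask
    never bleed in. Values outside the mask are returned unchanged.
    """
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.broadcast_to(
        np.asarray(spacing, float), (3,)
    )
    weight = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = tensors.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(3):
            for j in range(i, 3):
                comp = np.where(mask, tensors[..., i, j], 0.0)
                sm = ndimage.gaussian_filter(comp, sigma_vox)
                sm = np.where(weight > 1e-12, sm / weight, 0.0)
                out[..., i, j] = np.where(mask, sm, tensors[..., i, j])
                out[..., j, i] = out[..., i, j]
    return out


def spd_project(t: np.ndarray, floor: float) -> tuple[np.ndarray, int]:
    """Clamp eigenvalues below ``floor`` upward; returns (repaired, n_repaired).

    Used after operations (e.g. component-wise smoothing) that can produce
    slightly indefinite tensors at region boundaries.
    """
    ev, vec = np.linalg.eigh(t)
    bad = ev.min(axis=-1) < floor
    n = int(bad.sum())
    if n:
        ev = np.maximum(ev, floor)
        t = t.copy()
        t[bad] = np.einsum(
            "...ij,...j,...kj->...ik", vec[bad], ev[bad], vec[bad]
        )
    return t, n
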