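"""Diffusion-to-conductivity tensor mapping.

Two schemes convert water diffusion tensors D (mm^2/s) into conductivity
tensors sigma (S/m), both preserving eigenvectors:

* direct mapping: sigma = s * D with one global scale s chosen by least
  squares so that the voxel-averaged geometric-mean conductivity of WM and GM
  jointly matches the literature isotropic values,
      s = (s_WM sigma_WM^iso + s_GM sigma_GM^iso) / (s_WM^2 + s_GM^2),
  where s_WM/GM is the mean geometric eigenvalue of D over the tissue;
* volume-normalized mapping: per voxel, eigenvalues are rescaled as
  sigma_i = d_i / (d1 d2 d3)^(1/3) * sigma_tissue^iso, which matches the
  volume of the conductivity ellipsoid to the isotropic reference sphere.

The module also builds the isotropic tensor image and the smoothed
"ground-truth" conductivity tensor image (CTI) used to benchmark DT-MREIT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import (
    LabeledVolume,
    TensorField,
    geometric_mean_eigenvalues,
    smooth_tensor_components,
    spd_project,
)
from .tissues import ConductivityAssignment

__all__ = [
    "MappingResult",
    "mean_geometric_eigenvalue",
    "direct_mapping",
    "volume_normalized_mapping",
    "isotropic_tensor_field",
    "build_ground_truth_cti",
    "conductivity_field",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MappingResult:
    sigma: TensorField        # conductivity tensors, S/m
    scale: float              # global scale s (direct mapping)
    s_wm: float               # mean geometric eigenvalue of D over WM, mm^2/s
    s_gm: float               # same over GM


def mean_geometric_eigenvalue(D: TensorField, mask: np.ndarray) -> float:
    """Voxel-average of the geometric mean of the tensor eigenvalues on mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    t = D.tensors[mask]
    ev = np.linalg.eigvalsh(t)
    bad = ev[:, 0] <= 0
    if bad.any():
        idx = np.argwhere(mask)[bad]
        raise ValueError("non-SPD tensor inside mask at voxel "
                         f"{tuple(int(v) for v in idx[0])}")
    return float(np.cbrt(np.linalg.det(t)).mean())


def direct_mapping(D: TensorField, wm_mask, gm_mask,
                   assign: ConductivityAssignment) -> MappingResult:
    """sigma = s*D on GM and WM with one jointly least-squares-fitted scale s.

    s minimizes (s*s_WM - sigma_WM^iso)^2 + (s*s_GM - sigma_GM^iso)^2 and is
    therefore invariant to a global rescaling of D (sigma is unchanged).
    """
    wm_mask = np.asarray(wm_mask, bool)
    gm_mask = np.asarray(gm_mask, bool)
    if not wm_mask.any() or not gm_mask.any():
        raise ValueError("WM and GM masks must both be non-empty")
    s_wm = mean_geometric_eigenvalue(D, wm_mask)
    s_gm = mean_geometric_eigenvalue(D, gm_mask)
    s = (s_wm * assign.sigma("wm") + s_gm * assign.sigma("gm")) / (
        s_wm**2 + s_gm**2
    )
    assert s > 0, "scale must be positive for SPD tensors and positive targets"
    both = wm_mask | gm_mask
    tensors = np.zeros_like(D.tensors)
    tensors[both] = s * D.tensors[both]
    return MappingResult(
        TensorField(tensors, both, units="S/m"), float(s), s_wm, s_gm
    )


def volume_normalized_mapping(D: TensorField, wm_mask, gm_mask,
                              assign: ConductivityAssignment) -> TensorField:
    """Per-voxel eigenvalue rescaling so the geometric-mean conductivity of
    every voxel equals the tissue's isotropic literature value exactly."""
    wm_mask = np.asarray(wm_mask, bool)
    gm_mask = np.asarray(gm_mask, bool)
    if not wm_mask.any() or not gm_mask.any():
        raise ValueError("WM and GM masks must both be non-empty")
    tensors = np.zeros_like(D.tensors)
    for mask, tissue in ((wm_mask, "wm"), (gm_mask, "gm")):
        d = D.tensors[mask]
        gm_eig = np.cbrt(np.linalg.det(d))
        if np.any(gm_eig <= 0):
            idx = np.argwhere(mask)[gm_eig <= 0]
            raise ValueError(
                f"zero/negative eigenvalue product at voxel {tuple(int(v) for v in idx[0])}"
            )
        tensors[mask] = d / gm_eig[:, None, None] * assign.sigma(tissue)
    return TensorField(tensors, wm_mask | gm_mask, units="S/m")


def isotropic_tensor_field(labels: LabeledVolume,
                           assign: ConductivityAssignment,
                           overrides: dict | None = None) -> TensorField:
    """sigma = sigma_tissue^iso * I at every conducting voxel.

    ``overrides`` replaces individual tissue conductivities (used when
    sampling conductivities from the uncertainty priors).
    """
    values = dict(assign.iso)
    if overrides:
        values.update(overrides)
    present = [t for t, c in labels.tissues.items() if (labels.labels == c).any()]
    missing = [t for t in present if t not in values]
    if missing:
        raise ValueError(f"no conductivity assigned for tissues {missing}")
    tensors = np.zeros(labels.shape + (3, 3), float)
    eye = np.eye(3)
    for t in present:
        tensors[labels.mask(t)] = values[t] * eye
    return TensorField(tensors, labels.labels > 0, units="S/m")


def conductivity_field(labels: LabeledVolume, D: TensorField | None,
                       assign: ConductivityAssignment, scheme: str = "iso",
                       overrides: dict | None = None) -> TensorField:
    """Build the head conductivity tensor field for one mapping scheme.

    scheme "iso": every tissue isotropic; "direct": GM/WM anisotropic via the
    global-scale direct mapping; "volnorm": GM/WM anisotropic via per-voxel
    volume normalization. Non-brain tissues are always isotropic.
    ``overrides`` replaces individual tissue conductivities (e.g. samples
    from the uncertainty priors), entering the anisotropic schemes as the
    matching targets.
    """
    values = dict(assign.iso)
    if overrides:
        values.update(overrides)
    iso = isotropic_tensor_field(labels, assign, overrides)
    if scheme == "iso":
        return iso
    if D is None:
        raise ValueError(f"scheme {scheme!r} requires a diffusion tensor field")
    wm, gm = labels.mask("wm"), labels.mask("gm")
    assign2 = ConductivityAssignment({**values})
    if scheme == "direct":
        aniso = direct_mapping(D, wm, gm, assign2).sigma
    elif scheme == "volnorm":
        aniso = volume_normalized_mapping(D, wm, gm, assign2)
    else:
        raise ValueError(f"unknown mapping scheme {scheme!r}")
    tensors = iso.tensors.copy()
    both = wm | gm
    tensors[both] = aniso.tensors[both]
    return TensorField(tensors, labels.labels > 0, units="S/m")


def build_ground_truth_cti(
    D: TensorField,
    labels: LabeledVolume,
    assign: ConductivityAssignment,
    smoothing_fwhm_mm: float = 1.0,
    isotropic_brain: bool = False,
) -> TensorField:
    """Ground-truth conductivity tensor image for reconstruction benchmarks.

    GM and WM diffusion tensors are scaled linearly (separately per region)
    so that the region-average geometric-mean conductivity matches the
    literature value; CSF is isotropic. The result is then smoothed with a
    small Gaussian (per component, masked to brain+CSF with edge-renormalized
    kernels) to avoid step discontinuities in the simulated current density.
    Smoothing slightly shifts the region averages; tiny indefinite tensors it
    may create at boundaries are projected back to SPD and the count logged.

    With ``isotropic_brain`` the GM/WM/CSF tensors are matched isotropic
    instead (the comparison case), smoothed identically.
    """
    for t in ("gm", "wm", "csf"):
        if t not in labels.tissues or not labels.mask(t).any():
            raise ValueError("phantom must contain GM, WM and CSF")
    tensors = np.zeros(labels.shape + (3, 3), float)
    brain = labels.mask("gm", "wm", "csf")
    eye = np.eye(3)
    for t in ("gm", "wm"):
        tmask = labels.mask(t)
        if isotropic_brain:
            tensors[tmask] = assign.sigma(t) * eye
        else:
            c = assign.sigma(t) / mean_geometric_eigenvalue(D, tmask)
            tensors[tmask] = c * D.tensors[tmask]
    tensors[labels.mask("csf")] = assign.sigma("csf") * eye
    # remaining tissues: isotropic literature values, untouched by smoothing
    for t, code in labels.tissues.items():
        if t in ("gm", "wm", "csf"):
            continue
        tensors[labels.labels == code] = assign.sigma(t) * eye

    if smoothing_fwhm_mm > 0:
        tensors = smooth_tensor_components(tensors, brain, smoothing_fwhm_mm,
                                           labels.spacing)
        floor = 1e-6 * np.median(geometric_mean_eigenvalues(tensors[brain]))
        repaired, n = spd_project(tensors[brain], floor)
        if n:
            log.warning("SPD repair after CTI smoothing: %d voxels clamped", n)
            tensors[brain] = repaired
    return TensorField(tensors, labels.labels > 0, units="S/m")
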