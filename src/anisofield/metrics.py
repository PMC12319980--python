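"""Field-comparison summary metrics, all reported in percent.

Two conventions exist for relative differences between fields: the
root-of-ratio-of-sums-of-squares ("root" form, homogeneous of degree one: a
10% uniform scaling gives 10%) and the plain ratio of sums of squares
("squared" form). Both are provided everywhere; the root form is the
reporting default, while the squared form is the optimizer objective for the
B_z mismatch (the two are monotone-equivalent, so the minimizer is the same).
"""

from __future__ import annotations

import numpy as np

__all__ = ["relative_std", "relative_difference", "delta_bz", "relative_error"]


def _masked(a, mask):
    a = np.asarray(a, float)
    if mask is None:
        return a.ravel()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return a[mask]


def relative_std(mean_field, std_field, mask=None) -> float:
    """Summed standard deviation as a percentage of the summed mean magnitude:
    100 * sum(STD_i) / sum(|mean_i|). The uncertainty-band summary of a
    surrogate model over a region of interest."""
    m = _masked(mean_field, mask)
    s = _masked(std_field, mask)
    denom = np.abs(m).sum()
    if denom == 0:
        raise ValueError("mean field sums to zero on the mask")
    return float(s.sum() / denom * 100.0)


def relative_difference(field_a, field_b, mask=None, form="root") -> float:
    """Relative difference of field a vs reference b, in percent.

    form="root": 100*sqrt(sum((a-b)^2)/sum(b^2)); form="squared" drops the
    square root.
    """
    a = _masked(field_a, mask)
    b = _masked(field_b, mask)
    if a.shape != b.shape:
        raise ValueError("field shapes do not match")
    denom = (b**2).sum()
    if denom == 0:
        raise ValueError("reference field is identically zero on the mask")
    ratio = ((a - b) ** 2).sum() / denom
    if form == "root":
        return float(np.sqrt(ratio) * 100.0)
    if form == "squared":
        return float(ratio * 100.0)
    raise ValueError(f"unknown form {form!r}")


def delta_bz(bz_sim, bz_ref, mask=None, form="squared") -> float:
    """B_z mismatch 100*sum((Bz_sim - Bz_ref)^2)/sum(Bz_ref^2) (default), the
    objective of the conductivity fit; the root form is available for
    reporting."""
    return relative_difference(bz_sim, bz_ref, mask, form=form)


def relative_error(x_field, x_ref, mask=None, form="root") -> float:
    """Relative reconstruction error 100*sqrt(sum((x-ref)^2)/sum(ref^2))."""
    return relative_difference(x_field, x_ref, mask, form=form)
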