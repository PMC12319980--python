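import numpy as np
import pytest

from anisofield.grids import TensorField, geometric_mean_eigenvalues
from anisofield.mapping import (
    build_ground_truth_cti,
    conductivity_field,
    direct_mapping,
    isotropic_tensor_field,
    mean_geometric_eigenvalue,
    volume_normalized_mapping,
)
from anisofield.tissues import ConductivityAssignment


def random_spd_field(rng, shape, scale=1e-3):
    a = rng.normal(size=shape + (3, 3))
    t = a @ np.swapaxes(a, -1, -2) + 0.2 * np.eye(3)
    return TensorField(t * scale, units="mm^2/s")


class TestMeanGeometricEigenvalue:
    def test_isotropic_field_returns_diffusivity(self):
        d = 1.3e-3
        f = TensorField(np.broadcast_to(d * np.eye(3), (4, 4, 4, 3, 3)).copy())
        assert mean_geometric_eigenvalue(f, np.ones((4, 4, 4), bool)) == (
            pytest.approx(d, rel=1e-12)
        )

    def test_single_voxel_closed_form(self):
        f = TensorField(np.diag([1e-3, 2e-3, 4e-3])[None, None, None])
        got = mean_geometric_eigenvalue(f, np.ones((1, 1, 1), bool))
        assert got == pytest.approx(2e-3, rel=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        f = random_spd_field(rng, (5, 4, 3))
        mask = rng.random((5, 4, 3)) > 0.3
        ev = np.linalg.eigvalsh(f.tensors[mask])
        oracle = np.prod(ev, axis=-1) ** (1 / 3)
        assert mean_geometric_eigenvalue(f, mask) == pytest.approx(
            oracle.mean(), rel=1e-12
        )

    def test_non_spd_voxel_reported(self):
        t = np.broadcast_to(np.eye(3), (3, 3, 3, 3, 3)).copy()
        t[0, 1, 2] = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match=r"\(0, 1, 2\)"):
            mean_geometric_eigenvalue(TensorField(t), np.ones((3, 3, 3), bool))

    def test_empty_mask_rejected(self):
        f = TensorField(np.broadcast_to(np.eye(3), (2, 2, 2, 3, 3)).copy())
        with pytest.raises(ValueError, match="empty"):
            mean_geometric_eigenvalue(f, np.zeros((2, 2, 2), bool))


@pytest.fixture()
def two_tissue(assign):
    """Isotropic d*I diffusion tensors split into WM and GM halves."""
    d = 0.9e-3
    shape = (4, 4, 4)
    f = TensorField(np.broadcast_to(d * np.eye(3), shape + (3, 3)).copy())
    wm = np.zeros(shape, bool)
    gm = np.zeros(shape, bool)
    wm[:2] = True
    gm[2:] = True
    return f, wm, gm, d


class TestDirectMapping:
    def test_closed_form_scale_for_equal_tensors(self, two_tissue, assign):
        """With identical isotropic tensors in both tissues, the fitted scale
        collapses to s = (sigma_WM + sigma_GM)/(2 d)."""
        f, wm, gm, d = two_tissue
        res = direct_mapping(f, wm, gm, assign)
        s_expected = (0.126 + 0.275) / (2 * d)
        assert res.scale == pytest.approx(s_expected, rel=1e-12)
        np.testing.assert_allclose(
            res.sigma.tensors[wm | gm],
            np.broadcast_to(res.scale * d * np.eye(3), (int((wm | gm).sum()), 3, 3)),
            rtol=1e-12,
        )

    def test_scale_invariance_under_global_rescaling(self, assign):
        rng = np.random.default_rng(4)
        f = random_spd_field(rng, (4, 4, 4))
        wm = np.zeros((4, 4, 4), bool)
        gm = np.zeros((4, 4, 4), bool)
        wm[:2], gm[2:] = True, True
        res1 = direct_mapping(f, wm, gm, assign)
        res2 = direct_mapping(TensorField(7.0 * f.tensors), wm, gm, assign)
        assert res2.scale == pytest.approx(res1.scale / 7.0, rel=1e-12)
        np.testing.assert_allclose(res2.sigma.tensors, res1.sigma.tensors,
                                   rtol=1e-10)

    def test_scale_matches_brute_force_least_squares(self, assign):
        """The closed-form s equals the argmin of the 1-D quadratic found by
        grid refinement to 1e-6."""
        rng = np.random.default_rng(5)
        f = random_spd_field(rng, (4, 4, 4))
        wm = np.zeros((4, 4, 4), bool)
        gm = np.zeros((4, 4, 4), bool)
        wm[:2], gm[2:] = True, True
        res = direct_mapping(f, wm, gm, assign)

        def loss(s):
            return ((s * res.s_wm - assign.sigma("wm")) ** 2
                    + (s * res.s_gm - assign.sigma("gm")) ** 2)

        lo, hi = res.scale * 0.5, res.scale * 1.5
        for _ in range(40):
            grid = np.linspace(lo, hi, 51)
            best = grid[np.argmin([loss(s) for s in grid])]
            lo, hi = best - (hi - lo) / 50, best + (hi - lo) / 50
        assert res.scale == pytest.approx(best, rel=1e-6)

    def test_empty_mask_rejected(self, two_tissue, assign):
        f, wm, _, _ = two_tissue
        with pytest.raises(ValueError, match="non-empty"):
            direct_mapping(f, wm, np.zeros_like(wm), assign)


class TestVolumeNormalizedMapping:
    def test_isotropic_gm_maps_to_literature_value(self, two_tissue, assign):
        f, wm, gm, _ = two_tissue
        out = volume_normalized_mapping(f, wm, gm, assign)
        for mask, val in ((gm, 0.275), (wm, 0.126)):
            np.testing.assert_allclose(
                out.tensors[mask],
                np.broadcast_to(val * np.eye(3), (int(mask.sum()), 3, 3)),
                rtol=1e-12,
            )

    def test_geometric_mean_preserved_exactly(self, assign):
        rng = np.random.default_rng(6)
        f = random_spd_field(rng, (5, 5, 2))
        wm = np.zeros((5, 5, 2), bool)
        gm = np.zeros((5, 5, 2), bool)
        wm[:3], gm[3:] = True, True
        out = volume_normalized_mapping(f, wm, gm, assign)
        np.testing.assert_allclose(
            geometric_mean_eigenvalues(out.tensors[wm]), 0.126, rtol=1e-12
        )
        np.testing.assert_allclose(
            geometric_mean_eigenvalues(out.tensors[gm]), 0.275, rtol=1e-12
        )

    def test_eigenvectors_preserved(self, assign):
        rng = np.random.default_rng(7)
        f = random_spd_field(rng, (4, 4, 2))
        wm = np.zeros((4, 4, 2), bool)
        gm = np.zeros((4, 4, 2), bool)
        wm[:2], gm[2:] = True, True
        out = volume_normalized_mapping(f, wm, gm, assign)
        # sigma = c(voxel) * D, so eigenvector bases must agree (up to sign)
        _, vd = np.linalg.eigh(f.tensors[wm | gm])
        _, vs = np.linalg.eigh(out.tensors[wm | gm])
        dots = np.abs(np.einsum("...ij,...ij->...j", vd, vs))
        np.testing.assert_allclose(dots, 1.0, atol=1e-10)


class TestIsotropicField:
    def test_literature_values_assigned(self, head32, assign):
        labels, _ = head32
        out = isotropic_tensor_field(labels, assign)
        for tissue, val in (("csf", 1.654), ("scalp", 0.465)):
            got = out.tensors[labels.mask(tissue)]
            np.testing.assert_allclose(
                got, np.broadcast_to(val * np.eye(3), got.shape)
            )
        from anisofield.grids import fractional_anisotropy

        fa = fractional_anisotropy(out.tensors[labels.labels > 0])
        np.testing.assert_allclose(fa, 0.0, atol=1e-12)

    def test_unassigned_label_rejected(self, head32):
        labels, _ = head32
        bad = ConductivityAssignment({"scalp": 0.465})
        with pytest.raises(ValueError, match="no conductivity"):
            isotropic_tensor_field(labels, bad)


class TestGroundTruthCti:
    def test_region_mean_matched_before_smoothing(self, head32, assign):
        labels, D = head32
        cti = build_ground_truth_cti(D, labels, assign, smoothing_fwhm_mm=0.0)
        for t, val in (("wm", 0.126), ("gm", 0.275), ("csf", 1.654)):
            got = mean_geometric_eigenvalue(cti, labels.mask(t))
            assert got == pytest.approx(val, rel=1e-10)

    def test_smoothing_shifts_region_means_slightly(self, head32, assign):
        labels, D = head32
        cti = build_ground_truth_cti(D, labels, assign, smoothing_fwhm_mm=2.0)
        for t, val in (("wm", 0.126), ("gm", 0.275)):
            got = mean_geometric_eigenvalue(cti, labels.mask(t))
            shift = abs(got - val) / val
            assert 0.0 < shift < 0.20

    def test_output_spd(self, head32, assign):
        labels, D = head32
        cti = build_ground_truth_cti(D, labels, assign, smoothing_fwhm_mm=4.0)
        assert cti.is_spd()[labels.labels > 0].all()


class TestConductivityField:
    def test_unknown_scheme_rejected(self, head32, assign):
        labels, D = head32
        with pytest.raises(ValueError, match="unknown mapping scheme"):
            conductivity_field(labels, D, assign, "nope")

    def test_overrides_enter_all_schemes(self, head32, assign):
        labels, D = head32
        over = {"gm": 0.5, "wm": 0.2, "csf": 1.0}
        for scheme in ("iso", "direct", "volnorm"):
            out = conductivity_field(labels, D, assign, scheme, over)
            got = mean_geometric_eigenvalue(out, labels.mask("csf"))
            assert got == pytest.approx(1.0, rel=1e-10)
        vn = conductivity_field(labels, D, assign, "volnorm", over)
        assert mean_geometric_eigenvalue(vn, labels.mask("gm")) == (
            pytest.approx(0.5, rel=1e-10)
        )
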