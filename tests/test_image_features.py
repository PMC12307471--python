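"""Feature panel oracles: moments, co-occurrence, shape, spectral entropy."""

import numpy as np
import pytest

from serfe import (
    FeaturePanelSpec,
    VolumeROI,
    extract_panel,
    first_order_features,
    glcm_features,
    shape_features,
    spectral_entropy,
)
from serfe.errors import ValidationError


def _roi_from_values(values, shape=None):
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.size, 1, 1)
    vol = values.reshape(shape)
    return VolumeROI(vol, np.ones(shape), (1.0, 1.0, 1.0))


class TestFirstOrder:
    def test_closed_form_moments(self):
        f = first_order_features(_roi_from_values([2.0, 4.0, 6.0]))
        assert f["mean"] == pytest.approx(4.0)
        assert f["variance"] == pytest.approx(8.0 / 3.0)

    def test_constant_roi_conventions(self):
        f = first_order_features(_roi_from_values([5.0] * 8))
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
        assert f["histogram_entropy"] == 0.0

    def test_right_skewed_distribution(self):
        # moment formula evaluated directly on {0,0,0,0,10}
        x = np.array([0.0, 0, 0, 0, 10])
        f = first_order_features(_roi_from_values(x))
        var = x.var()
        expected = ((x - x.mean()) ** 3).mean() / var**1.5
        assert f["skewness"] == pytest.approx(expected)
        assert f["skewness"] > 0

    def test_invariant_to_axis_permutation(self, tumor_roi):
        permuted = VolumeROI(
            np.transpose(tumor_roi.intensities, (2, 0, 1)),
            np.transpose(tumor_roi.mask, (2, 0, 1)),
            tumor_roi.spacing,
        )
        a = first_order_features(tumor_roi)
        b = first_order_features(permuted)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestGLCM:
    def test_constant_roi_single_cell(self):
        f = glcm_features(_roi_from_values([3.0] * 10))
        assert f["energy"] == pytest.approx(1.0)
        assert f["contrast"] == 0.0

    def test_alternating_pattern_enumerated(self):
        # 0,1,0,1,... with 2 levels, distance 1 along the long axis:
        # every co-occurrence is (0,1) or (1,0), each with p = 0.5
        vals = np.array([0.0, 1.0] * 16)
        roi = _roi_from_values(vals)
        spec = FeaturePanelSpec(glcm_levels=2)
        f = glcm_features(roi, spec)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)

    def test_matrices_symmetric_and_normalized(self, tumor_roi):
        from serfe.image_features import DIRECTIONS_3D, _cooccurrence, _quantize

        q = _quantize(tumor_roi, 16)
        for angle in DIRECTIONS_3D:
            mat = _cooccurrence(q, angle, 16)
            assert mat is not None
            assert mat.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)

    def test_random_roi_feature_ranges(self, tumor_roi):
        f = glcm_features(tumor_roi)
        assert 0 < f["energy"] <= 1
        assert f["entropy"] >= 0


class TestShape:
    def test_single_voxel_closed_form(self):
        mask = np.zeros((5, 5, 5))
        mask[2, 2, 2] = 1
        roi = VolumeROI(np.ones((5, 5, 5)), mask, (1.0, 1.0, 1.0))
        f = shape_features(roi)
        assert f["volume_mm3"] == pytest.approx(1.0)
        assert f["surface_area_mm2"] == pytest.approx(6.0)
        assert f["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-12)

    @pytest.mark.parametrize("edge", [3, 7, 12])
    def test_cube_sphericity_independent_of_size(self, edge):
        shape = (edge + 4,) * 3
        mask = np.zeros(shape)
        mask[2 : 2 + edge, 2 : 2 + edge, 2 : 2 + edge] = 1
        roi = VolumeROI(np.ones(shape), mask, (1.0, 1.0, 1.0))
        f = shape_features(roi)
        assert f["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-9)

    @pytest.mark.parametrize("radius", [6, 10, 14])
    def test_digitized_ball_sphericity(self, radius):
        # face counting overestimates smooth surfaces by 3/2 (staircase
        # limit), so the digitized ball converges to sphericity 2/3, not 1
        n = 2 * radius + 5
        ax = np.arange(n) - n // 2
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = (xx**2 + yy**2 + zz**2) <= radius**2
        roi = VolumeROI(np.ones((n, n, n)), mask, (1.0, 1.0, 1.0))
        f = shape_features(roi)
        assert f["sphericity"] == pytest.approx(2.0 / 3.0, abs=0.05)
        # and the mm-scale quantities track the analytic ball
        assert f["volume_mm3"] == pytest.approx(4 / 3 * np.pi * radius**3, rel=0.1)
        assert f["surface_area_mm2"] == pytest.approx(6 * np.pi * radius**2, rel=0.1)

    def test_elongation_of_anisotropic_box(self):
        mask = np.zeros((20, 20, 20))
        mask[2:18, 2:10, 2:10] = 1  # 16 x 8 x 8 box
        roi = VolumeROI(np.ones((20, 20, 20)), mask, (1.0, 1.0, 1.0))
        f = shape_features(roi)
        assert f["elongation"] == pytest.approx(0.5, rel=0.05)


class TestSpectralEntropy:
    def test_constant_roi_zero(self):
        assert spectral_entropy(_roi_from_values([2.0] * 64)) == 0.0

    def test_pure_sinusoid_concentrated(self):
        t = np.arange(128)
        vals = np.sin(2 * np.pi * 8 * t / 128)
        h = spectral_entropy(_roi_from_values(vals))
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_white_noise_approaches_flat_spectrum_limit(self, rng):
        n = 4096
        vals = rng.standard_normal(n)
        h = spectral_entropy(_roi_from_values(vals))
        k = n // 2  # non-DC rfft bins
        assert np.log2(k) - 1.0 < h <= np.log2(k) + 1e-9


class TestExtractPanel:
    def test_deterministic(self, tumor_roi):
        a = extract_panel(tumor_roi)
        b = extract_panel(tumor_roi)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.feature_names == b.feature_names

    def test_panel_size_and_naming(self, tumor_roi):
        panel = extract_panel(tumor_roi)
        assert panel.n_features >= 20
        families = {n.split("_")[0] for n in panel.feature_names}
        assert {"firstorder", "glcm", "shape", "spectral"} <= families

    def test_family_toggles(self, tumor_roi):
        panel = extract_panel(tumor_roi, FeaturePanelSpec(include_glcm=False))
        assert not any(n.startswith("glcm_") for n in panel.feature_names)
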