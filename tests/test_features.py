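import numpy as np
import pytest

from anglemech.features import (
    MeasurementUndefinedError,
    RootNotFoundError,
    SurfaceNotFoundError,
    ValidationFailedError,
    ciliary_anterior_surface,
    circle_crossings,
    extract_alcb_features,
    extract_feature_row,
    extract_pb_features,
    extract_tpi_features,
    iris_centerline,
    iris_root_point,
    iris_thickness_on_circle,
)
from anglemech.geometry import (
    CILIARY,
    IRIS,
    SCLERA,
    AcquisitionMode,
    PhysicalSpacing,
    PixelPoint,
    SegmentationMask,
    physical_distance,
)
from anglemech.spur import SpurPoint, locate_scleral_spur
from anglemech.synthetic import AnatomyParams, render_mask
from conftest import make_band_mask

UNIT = PhysicalSpacing(1.0, 1.0)


def brute_force_crossings(contour, center, radius_um, spacing, step=0.01):
    """Dense contour marching oracle: sample every segment at `step` px and
    report sign changes of (distance - radius)."""
    sy, sx = spacing.um_per_px_y, spacing.um_per_px_x
    pts = []
    for i in range(len(contour) - 1):
        a, b = contour[i], contour[i + 1]
        seg_len = np.hypot(*(b - a))
        n = max(2, int(np.ceil(seg_len / step)) + 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        samples = a + t[:, None] * (b - a)
        d = np.hypot((samples[:, 0] - center.row) * sy, (samples[:, 1] - center.col) * sx)
        f = d - radius_um
        flips = np.flatnonzero(np.sign(f[1:]) != np.sign(f[:-1]))
        for k in flips:
            pts.append(0.5 * (samples[k] + samples[k + 1]))
    return np.array(pts)


class TestCircleCrossings:
    def test_far_square_has_no_crossings(self):
        square = np.array([[0, 0], [0, 4], [4, 4], [4, 0], [0, 0]], dtype=float)
        out = circle_crossings(square + 100, PixelPoint(0, 0), 10.0, UNIT)
        assert out == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random star-shaped closed contour about (50, 50)
        th = np.sort(rng.uniform(0, 2 * np.pi, 24))
        r = rng.uniform(10, 30, 24)
        pts = np.column_stack([50 + r * np.sin(th), 50 + r * np.cos(th)])
        contour = np.vstack([pts, pts[:1]])
        center = PixelPoint(50.0, 50.0)
        radius = float(rng.uniform(12, 28))
        exact = circle_crossings(contour, center, radius, UNIT)
        approx = brute_force_crossings(contour, center, radius, UNIT)
        assert len(exact) == len(approx)
        if exact:
            exact_arr = np.array([[p.row, p.col] for p in exact])
            d = np.linalg.norm(exact_arr - approx, axis=1)
            assert d.max() <= 0.05

    def test_translation_equivariance(self):
        square = np.array([[40, 40], [40, 60], [60, 60], [60, 40], [40, 40]], dtype=float)
        c1 = circle_crossings(square, PixelPoint(50, 50), 12.0, UNIT)
        c2 = circle_crossings(square + 7, PixelPoint(57, 57), 12.0, UNIT)
        for a, b in zip(c1, c2):
            assert b.row == pytest.approx(a.row + 7)
            assert b.col == pytest.approx(a.col + 7)

    def test_rejects_nonpositive_radius(self):
        square = np.array([[0, 0], [0, 4], [4, 4], [4, 0], [0, 0]], dtype=float)
        with pytest.raises(ValueError):
            circle_crossings(square, PixelPoint(0, 0), 0.0, UNIT)


class TestThicknessOnCircle:
    def test_uniform_band_transversal_crossing(self):
        # horizontal band rows 100..139 at 10 um/px: true thickness 400 um;
        # circle centred at band mid-row crosses it transversally at its
        # rightmost point
        mask = make_band_mask()
        center = PixelPoint(row=119.5, col=50.0)
        t = iris_thickness_on_circle(mask, center, 1000.0, toward=PixelPoint(119.5, 200.0))
        assert t == pytest.approx(400.0, abs=20.0)

    def test_circle_inside_sclera_only_is_undefined(self):
        mask = make_band_mask()
        with pytest.raises(MeasurementUndefinedError):
            iris_thickness_on_circle(mask, PixelPoint(row=25.0, col=256.0), 50.0)

    def test_resolution_consistency(self):
        # same physical scene and same physical circle center at two raster
        # resolutions: the measured thickness is a physical quantity
        params_lo = AnatomyParams()
        params_hi = AnatomyParams(width_px=2048, height_px=1310)
        got = {}
        for tag, p in [("lo", params_lo), ("hi", params_hi)]:
            mask, gt = render_mask(p, seed=0)
            got[tag] = iris_thickness_on_circle(mask, gt.spur, 500.0, toward=gt.root)
        assert abs(got["lo"] - got["hi"]) <= 10.0


class TestIrisRoot:
    def test_close_to_generator_truth(self, default_render):
        mask, gt = default_render
        root = iris_root_point(mask)
        assert np.hypot(root.row - gt.root.row, root.col - gt.root.col) <= 10.0

    def test_translation_equivariance(self, default_render):
        from test_spur import shift_labels

        mask, _ = default_render
        base = iris_root_point(mask)
        shifted = SegmentationMask(
            labels=shift_labels(mask.labels, 8, 6), mode=mask.mode, spacing=mask.spacing
        )
        moved = iris_root_point(shifted)
        assert moved.row == pytest.approx(base.row + 8)
        assert moved.col == pytest.approx(base.col + 6)

    def test_detached_iris_raises(self):
        mask = make_band_mask(ciliary_box=((250, 300), (300, 360)))  # far from iris
        with pytest.raises(RootNotFoundError):
            iris_root_point(mask)


class TestTpiFeatures:
    def test_recovers_generator_truth(self, default_render, default_row):
        _, gt = default_render
        pitch2 = 2 * 9.6  # two pixel pitches, um
        d = default_row.to_dict()
        assert d["it_spur500_um"] == pytest.approx(gt.it_spur500_um, abs=3 * pitch2)
        assert d["it_spur750_um"] == pytest.approx(gt.it_spur750_um, abs=pitch2)
        assert d["it_root500_um"] == pytest.approx(gt.it_root500_um, abs=pitch2)

    def test_wedge_profile_ordering_matches_analytic(self):
        params = AnatomyParams(iris_thickness_root_um=600, iris_thickness_pupil_um=300,
                               bowing_sagitta_um=0)
        mask, gt = render_mask(params, seed=1)
        spur = locate_scleral_spur(mask)
        feats = extract_tpi_features(mask, spur)
        assert (feats.it_spur500_um > feats.it_spur750_um) == (
            gt.it_spur500_um > gt.it_spur750_um
        )

    def test_spur_override_far_from_iris_gives_nan_markers(self, default_render):
        mask, _ = default_render
        fake = SpurPoint(point=PixelPoint(5.0, 1000.0), method="manual-override", quality=1.0)
        feats = extract_tpi_features(mask, fake)
        assert np.isnan(feats.it_spur500_um)
        assert np.isnan(feats.it_spur750_um)


class TestCenterline:
    def test_rectangular_band_near_straight(self):
        mask = make_band_mask()
        line = iris_centerline(mask)
        length = np.sum(np.hypot(*np.diff(line, axis=0).T))
        assert length == pytest.approx(512, rel=0.10)
        # near-straight: row excursion within the band
        assert np.ptp(line[:, 0]) <= 5.0

    def test_starts_at_root_end(self, default_render):
        mask, _ = default_render
        line = iris_centerline(mask)
        root = iris_root_point(mask)
        d0 = np.hypot(*(line[0] - root.as_array()))
        d1 = np.hypot(*(line[-1] - root.as_array()))
        assert d0 < d1

    def test_bowed_iris_sagitta(self):
        params = AnatomyParams(bowing_sagitta_um=300, boundary_jitter_px=0.0)
        mask, _ = render_mask(params, seed=0)
        line = iris_centerline(mask)
        sy, sx = mask.spacing.um_per_px_y, mask.spacing.um_per_px_x
        phys = np.column_stack([line[:, 1] * sx, line[:, 0] * sy])
        a, b = phys[0], phys[-1]
        u = (b - a) / np.linalg.norm(b - a)
        n = np.array([u[1], -u[0]])
        dev = np.abs((phys - a) @ n)
        # skeleton endpoints retract from the true surface ends, so compare
        # against the generator bowing with its stated 15% band
        assert dev.max() == pytest.approx(300, rel=0.15)


class TestPbFeatures:
    def test_flat_iris_zero_curvature(self):
        params = AnatomyParams(bowing_sagitta_um=0.0, boundary_jitter_px=0.0)
        mask, _ = render_mask(params, seed=0)
        spur = locate_scleral_spur(mask)
        feats = extract_pb_features(mask, spur)
        assert abs(feats.iris_curvature_um) <= 15.0

    def test_posterior_arc_sagitta(self):
        params = AnatomyParams(bowing_sagitta_um=250.0, boundary_jitter_px=0.0)
        mask, gt = render_mask(params, seed=0)
        spur = locate_scleral_spur(mask)
        feats = extract_pb_features(mask, spur)
        assert feats.iris_curvature_um == pytest.approx(250.0, abs=25.0)
        assert feats.iris_curvature_um == pytest.approx(gt.sagitta_um, abs=25.0)

    def test_negative_bowing_sign(self):
        params = AnatomyParams(bowing_sagitta_um=-100.0, boundary_jitter_px=0.0)
        mask, _ = render_mask(params, seed=0)
        spur = locate_scleral_spur(mask)
        assert extract_pb_features(mask, spur).iris_curvature_um == pytest.approx(-100, abs=20)

    def test_root_insertion_matches_truth(self, default_render, default_row):
        _, gt = default_render
        assert default_row.pb.root_insertion_um == pytest.approx(gt.root_insertion_um, abs=30.0)


class TestAlcbFeatures:
    @pytest.mark.parametrize("fraction", [0.25, 0.5, 0.75])
    def test_contact_fraction_recovery(self, fraction):
        mask, gt = render_mask(AnatomyParams(ciliary_contact_fraction=fraction), seed=2)
        feats = extract_alcb_features(mask)
        assert feats.contact_ratio == pytest.approx(gt.contact_ratio, abs=0.05)
        assert 0.0 <= feats.contact_ratio <= 1.0
        assert feats.contact_len_um <= feats.anterior_len_um

    def test_no_contact_case(self):
        mask, _ = render_mask(AnatomyParams(ciliary_contact_fraction=0.0), seed=2)
        assert extract_alcb_features(mask).contact_ratio <= 0.05

    def test_full_contact_case(self):
        mask, _ = render_mask(AnatomyParams(ciliary_contact_fraction=1.0), seed=2)
        assert extract_alcb_features(mask).contact_ratio >= 0.95

    def test_anterior_length_close_to_truth(self, default_render):
        mask, gt = default_render
        feats = extract_alcb_features(mask)
        assert feats.anterior_len_um == pytest.approx(gt.anterior_len_um, rel=0.10)

    def test_surface_translation_equivariance(self, default_render):
        from test_spur import shift_labels

        mask, _ = default_render
        s1 = ciliary_anterior_surface(mask)
        shifted = SegmentationMask(
            labels=shift_labels(mask.labels, 6, 9), mode=mask.mode, spacing=mask.spacing
        )
        s2 = ciliary_anterior_surface(shifted)
        assert len(s1) == pytest.approx(len(s2), abs=5)
        assert np.allclose(np.median(s2, axis=0) - np.median(s1, axis=0), [6, 9], atol=1.0)

    def test_isolated_ciliary_body_has_no_surface(self):
        labels = np.zeros((200, 200), dtype=np.uint8)
        labels[50:70, :] = SCLERA  # shell above, no iris anywhere
        labels[120:160, 60:140] = CILIARY
        mask = SegmentationMask(labels=labels, mode=AcquisitionMode.HALF_FRAME,
                                spacing=PhysicalSpacing(10.0, 10.0))
        with pytest.raises(SurfaceNotFoundError):
            ciliary_anterior_surface(mask)


class TestFeatureRow:
    def test_fully_populated_and_deterministic(self, default_render, default_row):
        mask, _ = default_render
        d = default_row.to_dict()
        for col in ("it_spur500_um", "it_spur750_um", "it_root500_um",
                    "iris_curvature_um", "root_insertion_um", "contact_ratio"):
            assert np.isfinite(d[col])
        again = extract_feature_row(mask, image_id="default").to_dict()
        assert d == again

    def test_invalid_mask_aborts_with_report(self, default_render):
        mask, _ = default_render
        labels = mask.labels.copy()
        labels[labels == CILIARY] = 0
        bad = SegmentationMask(labels=labels, mode=mask.mode, spacing=mask.spacing)
        with pytest.raises(ValidationFailedError) as err:
            extract_feature_row(bad)
        assert err.value.report.failures

    def test_mirror_then_renormalize_is_invariant(self, default_render, default_row):
        mask, _ = default_render
        mirrored = SegmentationMask(
            labels=mask.labels[:, ::-1].copy(), mode=mask.mode, spacing=mask.spacing
        )
        row = extract_feature_row(mirrored, image_id="default")
        a, b = default_row.values(), row.values()
        assert np.allclose(a, b, atol=9.6, equal_nan=True)  # one pixel pitch
        assert row.flipped is True

    def test_translation_invariance_of_measurements(self, default_render, default_row):
        from test_spur import shift_labels

        mask, _ = default_render
        shifted = SegmentationMask(
            labels=shift_labels(mask.labels, 7, 7), mode=mask.mode, spacing=mask.spacing
        )
        row = extract_feature_row(shifted, image_id="default")
        a, b = default_row.values(), row.values()
        # contact_ratio is dimensionless; physical features within one pitch
        assert np.allclose(a, b, atol=9.6, equal_nan=True)
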