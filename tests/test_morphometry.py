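import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sowscope import synth_scene as ss
from sowscope.calibration import CameraCalibration, ScaleCalibration
from sowscope.depth_io import DepthFrame, LineProbe
from sowscope.morphometry import (
    GIRTH_METHODS,
    BodyDimensions,
    MorphometryError,
    SideGeometry,
    girth,
    invert_side_silhouette,
    measure_dual_view,
    measure_side,
    measure_top,
    ramanujan_perimeter,
)


class TestGirthModels:
    def test_circle_limit_all_ellipse_methods(self):
        for method in ("ramanujan", "simple_ellipse", "stadium"):
            assert girth(20, 20, method).C == pytest.approx(20 * math.pi, rel=1e-9)

    def test_ramanujan_worked_value(self):
        est = girth(40, 30, "ramanujan")
        assert est.a == 20 and est.b == 15
        assert est.C == pytest.approx(math.pi * (105 - math.sqrt(4875)), rel=1e-12)
        assert est.C == pytest.approx(110.52, abs=0.01)
        # against the quadrature oracle
        assert est.C == pytest.approx(ss.ellipse_perimeter(20, 15), rel=1e-4)

    def test_stadium_worked_value(self):
        assert girth(40, 30, "stadium").C == pytest.approx(30 * math.pi + 20, rel=1e-12)

    def test_stadium_requires_width_major(self):
        with pytest.raises(MorphometryError, match="swap"):
            girth(30, 40, "stadium")

    def test_pig_empirical_is_affine(self):
        c0, c1 = 2.0, 1.5
        est = girth(40, 30, "pig_empirical", empirical_coeffs=(c0, c1))
        assert est.C == pytest.approx(c0 + c1 * 70)

    def test_unknown_method_and_bad_axes(self):
        with pytest.raises(MorphometryError):
            girth(40, 30, "hexagon")
        with pytest.raises(MorphometryError):
            girth(-1, 30)

    def test_ramanujan_tracks_quadrature_tightly_for_round_sections(self):
        # error grows ~ ((a-b)/(a+b))^6; a few 1e-7 at b/a = 0.6, 1e-12 near circular
        for ratio in np.linspace(0.6, 1.0, 21):
            a = 18.0
            b = ratio * a
            assert ramanujan_perimeter(a, b) == pytest.approx(
                ss.ellipse_perimeter(a, b), rel=1e-6
            )

    def test_ordering_against_bounds(self):
        for W, D in [(40, 30), (36, 28), (30, 15), (44, 40)]:
            a, b = W / 2, D / 2
            quad = ss.ellipse_perimeter(a, b)
            assert girth(W, D, "simple_ellipse").C <= girth(W, D, "ramanujan").C
            assert girth(W, D, "ramanujan").C <= quad * (1 + 1e-9)
            assert quad <= math.pi * math.sqrt(2 * (a**2 + b**2)) * (1 + 1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.floats(5, 50, allow_nan=False),
        st.floats(5, 50, allow_nan=False),
        st.floats(0.5, 5, allow_nan=False),
    )
    def test_symmetry_and_monotonicity(self, W, D, bump):
        for method in ("ramanujan", "simple_ellipse"):
            assert girth(W, D, method).C == pytest.approx(girth(D, W, method).C, rel=1e-12)
            assert girth(W + bump, D, method).C > girth(W, D, method).C
            assert girth(W, D + bump, method).C > girth(W, D, method).C


class TestBodyDimensions:
    def test_chest_depth_cannot_exceed_height(self):
        with pytest.raises(MorphometryError):
            BodyDimensions(L=90, W=30, H=40, D=45)

    def test_boundary_equality_allowed(self):
        dims = BodyDimensions(L=90, W=30, H=40, D=40)
        assert dims.D == dims.H

    def test_positive_dimensions_required(self):
        with pytest.raises(MorphometryError):
            BodyDimensions(L=0, W=30, H=40, D=30)


class TestMeasureTop:
    def test_constant_depth_field(self, constant_frame):
        cal = CameraCalibration(400.0)
        probes = [
            LineProbe((60, 10), (60, 210), "length"),  # 200 px -> capped by frame
            LineProbe((20, 80), (100, 80), "width"),
        ]
        # use an in-frame 200 px probe
        probes[0] = LineProbe((60, 10), (60, 110), "length")
        L, W = measure_top(constant_frame, cal, probes, depth_mode="mean")
        assert L == pytest.approx(100 * 1.4 / 400 * 100)
        assert W == pytest.approx(80 * 1.4 / 400 * 100)

    def test_missing_probe_is_reported(self, constant_frame):
        cal = CameraCalibration(400.0)
        with pytest.raises(MorphometryError, match="width"):
            measure_top(constant_frame, cal, [LineProbe((0, 0), (0, 10), "length")])

    def test_plane_mode_requires_chest_depth(self, constant_frame):
        cal = CameraCalibration(400.0)
        probes = [
            LineProbe((60, 10), (60, 110), "length"),
            LineProbe((20, 80), (100, 80), "width"),
        ]
        with pytest.raises(MorphometryError, match="chest depth"):
            measure_top(constant_frame, cal, probes, depth_mode="plane")


class TestMeasureSide:
    def test_scale_products(self):
        cal = ScaleCalibration(0.2)
        probes = [
            LineProbe((10, 50), (310, 50), "height"),       # 300 px
            LineProbe((40, 80), (160, 80), "chest_depth"),  # 120 px
        ]
        H, D, L_side = measure_side(probes, cal)
        assert H == pytest.approx(60.0)
        assert D == pytest.approx(24.0)
        assert L_side is None

    def test_chest_probe_equal_to_height_gives_boundary_dims(self):
        cal = ScaleCalibration(0.2)
        probes = [
            LineProbe((10, 50), (310, 50), "height"),
            LineProbe((10, 80), (310, 80), "chest_depth"),
        ]
        H, D, _ = measure_side(probes, cal)
        assert H == D


class TestSilhouetteInversion:
    @staticmethod
    def _tangent_rows(zc, h, w, geom):
        """Analytic tangent rows for an ellipse (w depth, h vertical) at
        the sagittal plane: solves (zcam + m*d − zc)² = h² + m²w² for m."""
        d = geom.distance
        # (zcam - zc + m d)^2 = h^2 + m^2 w^2
        q0 = geom.cam_height - zc
        A = d * d - w * w
        B = 2 * q0 * d
        C = q0 * q0 - h * h
        m1, m2 = np.roots([A, B, C])
        m_top, m_bot = max(m1, m2), min(m1, m2)
        return geom.principal_row - geom.focal_length * m_top, \
            geom.principal_row - geom.focal_length * m_bot

    def test_exact_recovery_from_analytic_tangents(self, side_geom):
        zc, h, w = 0.37, 0.13, 0.16
        r_top, r_bot = self._tangent_rows(zc, h, w, side_geom)
        H, D = invert_side_silhouette(r_top, r_bot, side_geom, half_width_m=w)
        assert H == pytest.approx(100 * (zc + h), rel=1e-10)
        assert D == pytest.approx(200 * h, rel=1e-10)

    def test_inverted_rows_rejected(self, side_geom):
        with pytest.raises(MorphometryError):
            invert_side_silhouette(300.0, 100.0, side_geom, 0.15)


class TestDualViewFusion:
    def test_noise_free_recovery_within_pixel_bound(
        self, top_rig, side_rig, top_cal, side_cal, side_geom
    ):
        cohort = ss.sample_cohort(5, seed=13)
        errs = {k: [] for k in "LWHD"}
        for scene in cohort:
            tf = ss.render_depth(scene, top_rig)
            sf = ss.render_depth(scene, side_rig)
            dims = measure_dual_view(
                tf, sf, top_cal, side_cal, side_geom,
                top_background_m=top_rig.standoff,
                side_background_m=side_rig.background_depth,
            )
            px_top = (
                (top_rig.standoff - scene.true_H / 100 + scene.true_D / 200)
                * 100 / top_rig.focal_length
            )
            px_side = side_cal.scale_factor
            errs["L"].append(abs(dims.L - scene.true_L) / px_top)
            errs["W"].append(abs(dims.W - scene.true_W) / px_top)
            errs["H"].append(abs(dims.H - scene.true_H) / px_side)
            errs["D"].append(abs(dims.D - scene.true_D) / px_side)
        for dim, e in errs.items():
            assert np.mean(e) <= 1.0, f"{dim}: mean error {np.mean(e):.2f} px"

    def test_literal_mean_depth_mode_underestimates_width(
        self, scene, top_frame, top_cal
    ):
        """The uncorrected field reading averages depth over the curved
        back, which sits above the chest mid-plane: W comes out low."""
        from sowscope.segmentation import BodyMask, extract_keypoints

        body = BodyMask(top_frame.counts < 1400)
        probes = extract_keypoints(body, "top")
        _, W_mean = measure_top(top_frame, top_cal, probes, depth_mode="mean")
        assert W_mean < scene.true_W * 0.95
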