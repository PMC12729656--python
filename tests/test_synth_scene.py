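import json
import math

import numpy as np
import pytest

from sowscope import synth_scene as ss
from sowscope.depth_io import read_depth
from sowscope.weight_models import REFERENCE_INTERCEPT, REFERENCE_SLOPE, bw1


class TestEllipsePerimeterOracle:
    def test_circle_limit(self):
        r = 13.7
        assert ss.ellipse_perimeter(r, r) == pytest.approx(2 * math.pi * r, rel=1e-9)

    def test_respects_classical_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.uniform(5, 25)
            b = rng.uniform(0.2, 1.0) * a
            C = ss.ellipse_perimeter(a, b)
            assert math.pi * (a + b) <= C <= math.pi * math.sqrt(2 * (a**2 + b**2))

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ss.SceneError):
            ss.ellipse_perimeter(0, 1)


class TestSceneTruth:
    def test_derived_dimensions(self, scene):
        assert scene.true_L == 90.0
        assert scene.true_W == 32.0
        assert scene.true_D == 26.0
        assert scene.true_H == 51.0  # clearance + chest depth
        assert scene.true_D <= scene.true_H

    def test_circular_cross_section_girth(self):
        s = ss.SceneTruth(
            pig_id="round", semi_length=45, semi_width=14, semi_height=14,
            clearance=25, true_weight=50,
        )
        assert s.true_C == pytest.approx(2 * math.pi * 14, rel=1e-9)

    def test_non_pig_aspect_rejected(self):
        with pytest.raises(ss.SceneError):
            ss.SceneTruth(
                pig_id="eel", semi_length=60, semi_width=10, semi_height=9,
                clearance=25, true_weight=50,
            )


class TestSampleCohort:
    def test_default_cohort_spans_study_weight_band(self):
        cohort = ss.sample_cohort(30, seed=11)
        assert len(cohort) == 30
        weights = [s.true_weight for s in cohort]
        assert all(30.0 <= w <= 100.0 for w in weights)

    def test_reproducible_for_identical_seed(self):
        a = ss.sample_cohort(10, seed=42)
        b = ss.sample_cohort(10, seed=42)
        assert [s.to_row() for s in a] == [s.to_row() for s in b]
        c = ss.sample_cohort(10, seed=43)
        assert [s.to_row() for s in a] != [s.to_row() for s in c]

    def test_noiseless_weight_matches_fusion_formula(self):
        (s,) = ss.sample_cohort(1, seed=3, sigma_w=0.0)
        expected = REFERENCE_SLOPE * bw1(s.true_C, s.true_L) + REFERENCE_INTERCEPT
        assert s.true_weight == pytest.approx(expected, abs=1e-12)

    def test_quadrature_girth_bounds_hold_across_cohort(self):
        for s in ss.sample_cohort(20, seed=9):
            a, b = s.semi_width, s.semi_height
            assert math.pi * (a + b) <= s.true_C <= math.pi * math.sqrt(2 * (a**2 + b**2))

    def test_invalid_range_names_offending_parameter(self):
        with pytest.raises(ss.SceneError, match="semi_width"):
            ss.sample_cohort(5, seed=0, param_ranges={"semi_width": (20.0, 12.0)})
        with pytest.raises(ss.SceneError, match="clearance"):
            ss.sample_cohort(5, seed=0, param_ranges={"clearance": (-1.0, 5.0)})
        with pytest.raises(ss.SceneError, match="unknown"):
            ss.sample_cohort(5, seed=0, param_ranges={"snout": (1, 2)})

    def test_n_below_one_rejected(self):
        with pytest.raises(ss.SceneError):
            ss.sample_cohort(0, seed=0)


class TestRenderDepth:
    def test_apex_depth_plus_height_equals_standoff(self, scene, top_frame, top_rig):
        body_min = top_frame.counts[top_frame.counts > 0].min()
        # Apex pixel: standoff − true_H, exact to one 1 mm count.
        expected = round((top_rig.standoff - scene.true_H / 100.0) * 1000)
        assert abs(int(body_min) - expected) <= 1

    def test_ground_pixels_at_standoff(self, top_frame, top_rig):
        corner = top_frame.counts[0, 0]
        assert corner == round(top_rig.standoff * 1000)

    def test_side_background_plane_depth(self, side_frame, side_rig):
        assert side_frame.counts[0, 0] == round(side_rig.background_depth * 1000)

    def test_silhouette_matches_body_pixels(self, scene, top_rig, top_frame):
        sil = ss.render_silhouette(scene, top_rig)
        body = top_frame.counts < round(top_rig.standoff * 1000)
        np.testing.assert_array_equal(sil, body)

    def test_out_of_view_raises_instead_of_cropping(self, top_rig):
        stray = ss.SceneTruth(
            pig_id="stray", semi_length=57, semi_width=16, semi_height=13,
            clearance=22, center_xy=(100.0, 0.0), true_weight=90,
        )
        with pytest.raises(ss.OutOfViewError):
            ss.render_depth(stray, top_rig)

    def test_render_roundtrip_recovers_length_at_known_depth(self, scene, top_frame, top_rig):
        """Pixel extent inverted through the pinhole at the known tangent
        plane recovers the true body length within one pixel-equivalent."""
        from sowscope.calibration import CameraCalibration, pixel_to_cm_top
        from sowscope.segmentation import BodyMask, extract_keypoints

        body = BodyMask(top_frame.counts < round(top_rig.standoff * 1000))
        probes = extract_keypoints(body, "top")
        length = next(p for p in probes if p.label == "length")
        d = top_rig.standoff - scene.true_H / 100.0 + scene.true_D / 200.0
        z_eff = math.sqrt(d**2 - (scene.true_D / 200.0) ** 2)
        cal = CameraCalibration(top_rig.focal_length)
        L = pixel_to_cm_top(length.pixel_length, z_eff, cal)
        px_equiv_cm = d * 100.0 / top_rig.focal_length
        assert abs(L - scene.true_L) <= px_equiv_cm


class TestApplyNoise:
    def test_zero_noise_is_identity(self, top_frame):
        out = ss.apply_noise(top_frame, ss.NoiseSpec(0.0, 0.0, seed=1))
        np.testing.assert_array_equal(out.counts, top_frame.counts)

    def test_hole_fraction_matches_rate(self):
        from sowscope.depth_io import DepthFrame

        frame = DepthFrame(counts=np.full((500, 500), 1000, dtype=np.uint16))
        out = ss.apply_noise(frame, ss.NoiseSpec(0.0, 0.10, seed=2))
        frac = (out.counts == 0).mean()
        assert abs(frac - 0.10) <= 0.01

    def test_same_seed_reproduces_exactly(self, top_frame):
        spec = ss.NoiseSpec(0.002, 0.02, seed=7)
        a = ss.apply_noise(top_frame, spec)
        b = ss.apply_noise(top_frame, spec)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = ss.apply_noise(top_frame, ss.NoiseSpec(0.002, 0.02, seed=8))
        assert (a.counts != c.counts).any()

    def test_noise_scale_grows_quadratically_with_depth(self):
        from sowscope.depth_io import DepthFrame

        near = DepthFrame(counts=np.full((200, 200), 500, dtype=np.uint16))
        far = DepthFrame(counts=np.full((200, 200), 2000, dtype=np.uint16))
        spec = ss.NoiseSpec(0.004, 0.0, seed=3)
        sd_near = ss.apply_noise(near, spec).counts.astype(float).std()
        sd_far = ss.apply_noise(far, spec).counts.astype(float).std()
        # sigma ratio should be (2.0/0.5)^2 = 16
        assert sd_far / sd_near == pytest.approx(16.0, rel=0.15)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ss.SceneError):
            ss.NoiseSpec(-0.001, 0.0)
        with pytest.raises(ss.SceneError):
            ss.NoiseSpec(0.001, 1.0)


@pytest.fixture(scope="module")
def cohort3():
    return ss.sample_cohort(3, seed=21)


class TestWriteFixture:
    def test_file_inventory(self, cohort3, tmp_path):
        manifest = ss.write_fixture(cohort3, tmp_path / "fx", seed=21)
        files = manifest["files"]
        assert sum(f.endswith("_top.png") for f in files) == 3
        assert sum(f.endswith("_side.png") for f in files) == 3
        assert sum(f.endswith("_mask.png") for f in files) == 3
        assert "truth.csv" in files
        assert (tmp_path / "fx" / "manifest.json").exists()
        for f in files:
            assert (tmp_path / "fx" / f).exists()

    def test_truth_csv_round_trip(self, cohort3, tmp_path):
        ss.write_fixture(cohort3, tmp_path / "fx", seed=21)
        back = ss.read_truth_csv(tmp_path / "fx" / "truth.csv")
        for orig, rec in zip(cohort3, back):
            assert rec.to_row() == orig.to_row()

    def test_rerun_with_manifest_seed_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            seed = json.loads('{"seed": 21}')["seed"]
            ss.write_fixture(ss.sample_cohort(3, seed=seed), tmp_path / d, seed=seed)
        assert (tmp_path / "a" / "truth.csv").read_bytes() == (
            tmp_path / "b" / "truth.csv"
        ).read_bytes()
        assert (tmp_path / "a" / "pig000_top.png").read_bytes() == (
            tmp_path / "b" / "pig000_top.png"
        ).read_bytes()

    def test_depth_images_read_back(self, cohort3, tmp_path):
        ss.write_fixture(cohort3, tmp_path / "fx", seed=21)
        frame = read_depth(tmp_path / "fx" / "pig000_top.png")
        assert frame.shape == (480, 848)
        assert frame.valid.all()

    def test_unwritable_path_fails_loudly(self, cohort3, tmp_path):
        blocker = tmp_path / "file"
        blocker.write_text("")
        with pytest.raises(OSError):
            ss.write_fixture(cohort3, blocker / "sub")
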