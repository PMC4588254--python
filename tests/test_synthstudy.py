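"""Template, displacement forward model, noise, and recovery evaluation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from pelvimetrix.coords import ValidationError
from pelvimetrix.measurement import measure_displacement, rotation_indicator
from pelvimetrix.synthstudy import (
    DisplacementDistribution,
    DisplacementSpec,
    PIVOT_CHOICES,
    TEMPLATE_LANDMARKS,
    add_marking_noise,
    default_template,
    displace,
    evaluate_recovery,
    render_sheets,
    simulate_study,
    true_rotation_class,
    SimulatedStudy,
    SimulatedSubject,
)

#: Anatomical direction named by each signed rotation axis (canonical-table
#: convention), used for the exhaustive sign-table check.
DIRECTIONS = {
    ("rot_x_deg", +1): ("sagittal", "extension"),
    ("rot_x_deg", -1): ("sagittal", "flexion"),
    ("rot_y_deg", +1): ("inlet", "internal"),
    ("rot_y_deg", -1): ("inlet", "external"),
    ("rot_z_deg", +1): ("outlet", "varus"),
    ("rot_z_deg", -1): ("outlet", "valgus"),
}


class TestTemplate:
    def test_mirror_symmetric_about_midplane(self):
        t = default_template()
        for name in TEMPLATE_LANDMARKS:
            left = np.asarray(t.landmarks[(name, "left")])
            right = np.asarray(t.landmarks[(name, "right")])
            np.testing.assert_allclose(left, right * [-1, 1, 1], atol=1e-12)
        np.testing.assert_allclose(
            t.landmarks[("sacral_endplate_centre", "midline")], (0, 0, 0))

    def test_zero_displacement_measures_zero_everywhere(self):
        report = measure_displacement(render_sheets(default_template(), "right", "P0"))
        assert report.translation.vertical_mm == pytest.approx(0, abs=1e-9)
        assert report.rotation.sagittal_mm == pytest.approx(0, abs=1e-9)
        assert report.rotation.inlet_mm == pytest.approx(0, abs=1e-9)
        assert report.rotation.outlet_mm == pytest.approx(0, abs=1e-9)

    def test_landmark_spans_within_anatomical_bounds(self):
        # Gross sanity bounds for an adult pelvis (mm).
        t = default_template()
        asis_l = np.asarray(t.landmarks[("ASIS", "left")])
        asis_r = np.asarray(t.landmarks[("ASIS", "right")])
        assert 180 < np.linalg.norm(asis_l - asis_r) < 320
        for name in TEMPLATE_LANDMARKS:
            assert np.linalg.norm(t.landmarks[(name, "left")]) < 250
        assert 35 < t.fh_diameter_mm < 65

    def test_overrides_and_unknown_key_rejected(self):
        t = default_template({"ASIS": (-120, 50, 90)})
        assert t.landmarks[("ASIS", "left")] == (120.0, 50.0, 90.0)
        with pytest.raises(ValidationError):
            default_template({"coccyx": (0, 0, 0)})


class TestDisplace:
    def test_zero_spec_is_identity(self):
        t = default_template()
        t2 = displace(t, DisplacementSpec("left"))
        for key in t.landmarks:
            np.testing.assert_allclose(t2.landmarks[key], t.landmarks[key], atol=1e-12)

    def test_pure_translation_moves_only_injured_side(self):
        t = default_template()
        t2 = displace(t, DisplacementSpec("left", ty=10.0))
        for name in TEMPLATE_LANDMARKS:
            orig = np.asarray(t.landmarks[(name, "left")])
            moved = np.asarray(t2.landmarks[(name, "left")])
            np.testing.assert_allclose(moved - orig, (0, 10, 0), atol=1e-12)
            np.testing.assert_allclose(
                t2.landmarks[(name, "right")], t.landmarks[(name, "right")], atol=1e-12)

    @pytest.mark.parametrize("pivot", PIVOT_CHOICES)
    def test_rotation_preserves_injured_side_rigidity(self, pivot, rng):
        t = default_template()
        spec = DisplacementSpec("right", rot_x_deg=9, rot_y_deg=-14, rot_z_deg=6,
                                pivot=pivot)
        t2 = displace(t, spec)
        before = pdist(t.side_points("right"))
        after = pdist(t2.side_points("right"))
        np.testing.assert_allclose(after, before, atol=1e-9)


class TestRenderAndNoise:
    def test_sacral_centre_shares_u_between_inlet_and_outlet(self):
        sheet = render_sheets(default_template(), "left", "P0")
        u_inlet = sheet.get("inlet", "sacral_endplate_centre", "midline").u
        u_outlet = sheet.get("outlet", "sacral_endplate_centre", "midline").u
        assert u_inlet == pytest.approx(u_outlet, abs=1e-9)

    def test_round_trip_recovers_pure_translation_exactly(self):
        spec = DisplacementSpec("right", tx=-8.0, ty=17.0, tz=-5.0)
        report = measure_displacement(
            render_sheets(displace(default_template(), spec), "right", "P1"))
        assert report.translation.vertical_mm == pytest.approx(17.0, abs=1e-9)
        assert report.translation.ap_mm == pytest.approx(-5.0, abs=1e-9)
        # right-side world -x is lateral
        assert report.translation.transverse_mm == pytest.approx(8.0, abs=1e-9)

    def test_zero_noise_returns_same_sheet(self):
        sheet = render_sheets(default_template(), "left", "P0")
        assert add_marking_noise(sheet, 0.0, 3) is sheet

    def test_same_seed_same_noise(self):
        sheet = render_sheets(default_template(), "left", "P0")
        a = add_marking_noise(sheet, 1.0, 42)
        b = add_marking_noise(sheet, 1.0, 42)
        assert a.points == b.points

    def test_negative_sd_rejected(self):
        sheet = render_sheets(default_template(), "left", "P0")
        with pytest.raises(ValidationError):
            add_marking_noise(sheet, -0.1, 0)

    def test_empirical_rms_miss_distance_matches_sd(self):
        # sd_mm parameterises the RMS of the 2D miss distance; use a
        # single-landmark sheet so 10,000 perturbations stay cheap.
        from pelvimetrix.coords import Point2
        from pelvimetrix.measurement import Calibration, LandmarkSheet

        sheet = LandmarkSheet(
            "T", "left",
            {"inlet": {("ASIS", "intact"): Point2(200.0, 300.0, "px")}},
            {"inlet": Calibration(fh_true_mm=48.0, fh_px=96.0)},  # 0.5 mm/px
        )
        rng = np.random.default_rng(7)
        ref = sheet.get("inlet", "ASIS", "intact")
        miss_sq = []
        for _ in range(10_000):
            p = add_marking_noise(sheet, 1.5, rng).get("inlet", "ASIS", "intact")
            miss_sq.append(((p.u - ref.u) ** 2 + (p.v - ref.v) ** 2) * 0.5**2)
        rms = np.sqrt(np.mean(miss_sq))
        assert rms == pytest.approx(1.5, rel=0.02)


class TestSignTable:
    @pytest.mark.parametrize("axis,sign", list(DIRECTIONS))
    def test_rotation_direction_classified_correctly(self, axis, sign):
        """A single-axis rotation must be named correctly for every pivot,
        side and magnitude in the unstable-fracture range."""
        plane, expected = DIRECTIONS[(axis, sign)]
        t = default_template()
        for side in ("left", "right"):
            for pivot in PIVOT_CHOICES:
                for angle in (5, 10, 20):
                    spec = DisplacementSpec(side, **{axis: sign * angle}, pivot=pivot)
                    report = measure_displacement(
                        render_sheets(displace(t, spec), side, "P"))
                    got = getattr(report.rotation, f"{plane}_class")
                    assert got == expected, (axis, sign, side, pivot, angle)


class TestSimulateStudy:
    def test_study_shape_and_determinism(self):
        a = simulate_study(n_subjects=6, n_raters=3, noise_sd_mm=1.0, seed=99)
        b = simulate_study(n_subjects=6, n_raters=3, noise_sd_mm=1.0, seed=99)
        assert len(a.subjects) == 6
        assert set(a.rater_sheets) == {"rater1", "rater2", "rater3"}
        for r in a.rater_sheets:
            for sa, sb in zip(a.rater_sheets[r], b.rater_sheets[r]):
                assert sa.points == sb.points
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.spec == sb.spec

    def test_different_raters_get_independent_noise(self):
        study = simulate_study(n_subjects=4, n_raters=2, noise_sd_mm=1.0, seed=1)
        assert study.rater_sheets["rater1"][0].points != study.rater_sheets["rater2"][0].points

    def test_displacements_respect_caps(self):
        study = simulate_study(n_subjects=40, n_raters=2, noise_sd_mm=0.0, seed=3)
        for s in study.subjects:
            assert max(abs(s.spec.tx), abs(s.spec.ty), abs(s.spec.tz)) <= 30.0
            assert max(abs(s.spec.rot_x_deg), abs(s.spec.rot_y_deg),
                       abs(s.spec.rot_z_deg)) <= 20.0

    def test_degenerate_distribution_flagged(self):
        dist = DisplacementDistribution(trans_sd_dominant=0, trans_sd_other=0,
                                        rot_sd_dominant=0, rot_sd_other=0)
        with pytest.warns(UserWarning, match="degenerate"):
            simulate_study(n_subjects=3, n_raters=2, seed=0, distribution=dist)

    def test_too_small_study_rejected(self):
        with pytest.raises(ValidationError):
            simulate_study(n_subjects=1, n_raters=5, seed=0)


class TestEvaluateRecovery:
    @staticmethod
    def _reports(study):
        return {r: {sh.subject_id: measure_displacement(sh) for sh in sheets}
                for r, sheets in study.rater_sheets.items()}

    def test_zero_noise_translational_rmse_is_zero(self):
        # Pure translations only: rotations off.
        dist = DisplacementDistribution(rot_sd_dominant=0, rot_sd_other=0)
        study = simulate_study(n_subjects=10, n_raters=2, noise_sd_mm=0.0,
                               seed=21, distribution=dist)
        rec = evaluate_recovery(study, self._reports(study))
        for pr in rec.translation.values():
            assert pr.rmse_mm == pytest.approx(0.0, abs=1e-9)
            assert pr.bias_mm == pytest.approx(0.0, abs=1e-9)

    def test_ten_degree_rotations_classified_with_high_accuracy(self):
        """Single-axis 10 deg rotations, 1 mm marking noise: >= 95% of the
        rated cases must carry the correct direction label."""
        t = default_template()
        rng = np.random.default_rng(2024)
        subjects = []
        keys = list(DIRECTIONS)
        for i in range(200):
            axis, sign = keys[i % 6]
            side = "left" if i % 2 == 0 else "right"
            spec = DisplacementSpec(side, **{axis: sign * 10.0})
            sheet = render_sheets(displace(t, spec), side, f"R{i:03d}")
            subjects.append(SimulatedSubject(sheet.subject_id, spec, sheet))
        study = SimulatedStudy(tuple(subjects), {"rater1": [
            add_marking_noise(s.sheet, 1.0, rng) for s in subjects
        ]}, seed=0, noise_sd_mm=1.0, mm_per_px=0.5)
        # accuracy on the displaced plane: check each subject's own axis
        hits = 0
        for s, noisy in zip(study.subjects, study.rater_sheets["rater1"]):
            axis = [a for a in ("rot_x_deg", "rot_y_deg", "rot_z_deg")
                    if getattr(s.spec, a) != 0][0]
            plane, expected = DIRECTIONS[(axis, int(np.sign(getattr(s.spec, axis))))]
            report = measure_displacement(noisy)
            hits += getattr(report.rotation, f"{plane}_class") == expected
        assert hits / len(study.subjects) >= 0.95

    def test_truth_class_uses_indicator_when_angle_is_zero(self):
        t = default_template()
        spec = DisplacementSpec("left", rot_x_deg=15.0)  # sagittal only
        sheet = render_sheets(displace(t, spec), "left", "P")
        # inlet/outlet true angles are zero; truth falls back to the
        # noiseless indicator's class (neutral unless cross-coupling is large)
        assert true_rotation_class(spec, sheet, "sagittal") == "extension"
        ind_inlet = rotation_indicator(sheet, "inlet")
        expected = "neutral" if abs(ind_inlet) <= 2 else None
        if expected:
            assert true_rotation_class(spec, sheet, "inlet") == "neutral"

    def test_subject_mismatch_rejected(self):
        study = simulate_study(n_subjects=4, n_raters=2, noise_sd_mm=0.5, seed=8)
        reports = self._reports(study)
        del reports["rater1"][study.subjects[0].subject_id]
        with pytest.raises(ValidationError, match="subject set mismatch"):
            evaluate_recovery(study, reports)
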