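import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from facebmi.exceptions import DegenerateInputError
from facebmi.io import LandmarkSet
from facebmi.metrics import (
    TemplateRoleMap,
    align_interpupillary,
    cheek_to_jaw,
    metrics_table,
    perimeter_to_area,
    width_to_height,
)
from facebmi.synthetic import SyntheticConfig, face_template, generate_landmarks, sample_population


def _lm(points):
    return LandmarkSet("t", np.asarray(points, float))


def _poly_roles(n_outline):
    """Roles for a polygon test face: points 0/1 are pupils, the rest the
    outline chain; eyelid/lip roles are dummies pointing at existing indices."""
    return TemplateRoleMap(
        left_pupil=0,
        right_pupil=1,
        outline=list(range(2, 2 + n_outline)),
        upper_eyelids=[0],
        upper_lip=[2],
        lip_corners=(2, 3),
    )


class TestPerimeterToArea:
    def test_unit_square(self):
        # polygon: left pupil (0,0) -> outline (0,1),(1,1) -> right pupil (1,0)
        lm = _lm([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert perimeter_to_area(lm, _poly_roles(2)) == pytest.approx(4.0)

    def test_regular_hexagon_matches_shoelace_oracle(self):
        ang = np.deg2rad(np.arange(6) * 60.0)
        v = np.column_stack([np.cos(ang), np.sin(ang)])
        # pupils are two adjacent vertices; the other four form the outline
        pts = np.vstack([v[0], v[5], v[1], v[2], v[3], v[4]])
        roles = TemplateRoleMap(0, 1, [2, 3, 4, 5], [0], [2], (2, 3))
        # independent oracle: shoelace on the listed vertices
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert perimeter_to_area(_lm(pts), roles) == pytest.approx(6.0 / area)
        assert perimeter_to_area(_lm(pts), roles) == pytest.approx(2.3094, abs=1e-4)

    @pytest.mark.parametrize("s", [0.5, 2.0, 17.0])
    def test_scales_as_inverse_length(self, s):
        lm = _lm([(0, 0), (1, 0), (0, 1), (1, 1)])
        scaled = _lm(lm.points * s)
        assert perimeter_to_area(scaled, _poly_roles(2)) == pytest.approx(4.0 / s)


class TestWidthToHeight:
    def _face(self):
        # 0,1 pupils; 2,3 lateral; 4,5 upper eyelids; 6,7 upper lip
        pts = [(-10, 120), (10, 120), (-50, 150), (50, 150),
               (0, 100), (-5, 90), (0, 180), (3, 185)]
        roles = TemplateRoleMap(
            0, 1, outline=[2, 3], upper_eyelids=[4, 5], upper_lip=[6, 7],
            lip_corners=(6, 7), lateral_candidates=[2, 3],
        )
        return _lm(pts), roles

    def test_printed_example(self):
        lm, roles = self._face()
        # width 100, eyelid bottom y=100, lip top y=180 -> 100/80
        assert width_to_height(lm, roles) == pytest.approx(1.25)

    def test_uniform_scaling_leaves_ratio_unchanged(self):
        lm, roles = self._face()
        assert width_to_height(_lm(lm.points * 2.0), roles) == pytest.approx(1.25)

    def test_zero_height_is_degenerate(self):
        lm, roles = self._face()
        pts = lm.points.copy()
        pts[6:, 1] = 100.0  # lip top at eyelid level
        with pytest.raises(DegenerateInputError):
            width_to_height(_lm(pts), roles)


class TestCheekToJaw:
    def _face(self, lip_y):
        # outline: left temple -> chin -> right temple
        outline = [(-50, 0), (-40, 100), (0, 140), (40, 100), (50, 0)]
        pts = [(-10, 60), (10, 60)] + outline + [(-20, lip_y), (20, lip_y)]
        roles = TemplateRoleMap(
            0, 1, outline=[2, 3, 4, 5, 6], upper_eyelids=[0, 1],
            upper_lip=[7, 8], lip_corners=(7, 8),
        )
        return _lm(pts), roles

    def test_exact_vertex_at_lip_height(self):
        lm, roles = self._face(lip_y=100.0)
        assert cheek_to_jaw(lm, roles) == pytest.approx(100.0 / 80.0)

    def test_interpolated_jaw_width(self):
        lm, roles = self._face(lip_y=50.0)
        # crossing halfway along the (-50,0)-(-40,100) segment: x = -45
        assert cheek_to_jaw(lm, roles) == pytest.approx(100.0 / 90.0)

    def test_uniform_scaling_leaves_ratio_unchanged(self):
        lm, roles = self._face(lip_y=100.0)
        assert cheek_to_jaw(_lm(lm.points * 3.0), roles) == pytest.approx(1.25)


class TestAlignment:
    def _gen_face(self, seed=3):
        cfg = SyntheticConfig(n_subjects=20, seed=seed, template_points=30,
                              image_size=64)
        subjects, truth = sample_population(cfg)
        tpl = face_template(30, 64)
        lm = generate_landmarks(subjects[0], truth, cfg, tpl)
        return lm, tpl.roles

    def test_target_ipd_and_idempotence(self):
        lm, roles = self._gen_face()
        a1 = align_interpupillary(lm, roles, target_ipd=90.0)
        d = np.linalg.norm(a1.points[roles.right_pupil] - a1.points[roles.left_pupil])
        assert d == pytest.approx(90.0, abs=1e-9)
        a2 = align_interpupillary(a1, roles, target_ipd=90.0)
        np.testing.assert_allclose(a2.points, a1.points, atol=1e-9)

    def test_rotated_input_pupils_level(self):
        lm, roles = self._gen_face()
        ang = np.deg2rad(30.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot = LandmarkSet("r", lm.points @ R.T)
        out = align_interpupillary(rot, roles)
        assert out.points[roles.left_pupil, 1] == pytest.approx(
            out.points[roles.right_pupil, 1], abs=1e-9
        )

    def test_coincident_pupils_degenerate(self):
        lm, roles = self._gen_face()
        pts = lm.points.copy()
        pts[roles.right_pupil] = pts[roles.left_pupil]
        with pytest.raises(DegenerateInputError):
            align_interpupillary(LandmarkSet("d", pts), roles)

    @hsettings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-np.pi, np.pi),
        scale=st.floats(0.2, 5.0),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
    )
    def test_metrics_invariant_under_input_similarity(self, angle, scale, tx, ty):
        """After interpupillary alignment all three metrics are invariant to
        any similarity transform of the raw landmarks."""
        lm, roles = self._gen_face()
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        moved = LandmarkSet("m", scale * lm.points @ R.T + [tx, ty])
        base = metrics_table([lm], roles).iloc[0]
        got = metrics_table([moved], roles).iloc[0]
        np.testing.assert_allclose(got.values, base.values, rtol=1e-9)


class TestMetricsTable:
    def test_matches_single_face_operations(self):
        cfg = SyntheticConfig(n_subjects=20, seed=5, template_points=30, image_size=64)
        subjects, truth = sample_population(cfg)
        tpl = face_template(30, 64)
        faces = [generate_landmarks(s, truth, cfg, tpl) for s in subjects[:5]]
        table = metrics_table(faces, tpl.roles)
        assert len(table) == 5 and np.isfinite(table.to_numpy()).all()
        for face in faces:
            aligned = align_interpupillary(face, tpl.roles)
            row = table.loc[face.subject_id]
            assert row["perimeter_to_area"] == pytest.approx(
                perimeter_to_area(aligned, tpl.roles)
            )
            assert row["width_to_height"] == pytest.approx(
                width_to_height(aligned, tpl.roles)
            )
            assert row["cheek_to_jaw"] == pytest.approx(
                cheek_to_jaw(aligned, tpl.roles)
            )

    def test_empty_input_gives_empty_table(self):
        tpl = face_template(30, 64)
        assert metrics_table([], tpl.roles).empty

    def test_lateral_extremes_match_all_point_scan(self):
        """On template faces the most lateral points over the outline chain
        coincide with a brute-force scan over every landmark."""
        cfg = SyntheticConfig(n_subjects=20, seed=9, template_points=30, image_size=64)
        subjects, truth = sample_population(cfg)
        tpl = face_template(30, 64)
        for s in subjects[:8]:
            lm = align_interpupillary(
                generate_landmarks(s, truth, cfg, tpl), tpl.roles
            )
            xs_all = lm.points[:, 0]
            xs_outline = lm.points[tpl.roles.lateral_candidates, 0]
            assert xs_outline.max() == pytest.approx(xs_all.max())
            assert xs_outline.min() == pytest.approx(xs_all.min())

    def test_role_map_yaml_roundtrip(self, tmp_path):
        tpl = face_template(30, 64)
        p = tmp_path / "roles.yaml"
        tpl.roles.to_yaml(p)
        back = TemplateRoleMap.from_yaml(p)
        assert back.outline == tpl.roles.outline
        assert back.lip_corners == tpl.roles.lip_corners
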