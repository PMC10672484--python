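"""Acetabular index geometry: reference lines, angles, diagnosis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelvikit import (
    AcIMeasurement,
    LandmarkSet,
    classify_ddh,
    compute_aci,
    hilgenreiner_vector,
    roof_vector,
)
from pelvikit.errors import DegenerateLandmarksError, InvalidThresholdError

from conftest import random_landmark_sets


def lm(ru, rd, lu, ld) -> LandmarkSet:
    return LandmarkSet(RU=ru, RD=rd, LU=lu, LD=ld)


class TestReferenceVectors:
    @pytest.mark.parametrize(
        "rd, ld, expected",
        [((100, 200), (300, 200), (200, 0)), ((0, 0), (0, 10), (0, 10))],
    )
    def test_hilgenreiner_is_ld_minus_rd(self, rd, ld, expected):
        v = hilgenreiner_vector(lm((50, 150), rd, (350, 150), ld))
        assert tuple(v) == expected

    def test_coincident_triradiate_points_are_degenerate(self):
        with pytest.raises(DegenerateLandmarksError):
            hilgenreiner_vector(lm((1, 1), (5, 5), (2, 2), (5, 5)))

    @pytest.mark.parametrize(
        "side, expected",
        [("right", (-40, -30)), ("left", (40, -30))],
    )
    def test_roof_vector_points_from_triradiate_to_lateral_edge(self, side, expected):
        landmarks = lm((80, 180), (120, 210), (340, 170), (300, 200))
        assert tuple(roof_vector(landmarks, side)) == expected

    def test_coincident_roof_points_are_degenerate(self):
        with pytest.raises(DegenerateLandmarksError):
            roof_vector(lm((120, 210), (120, 210), (340, 170), (300, 200)), "right")

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            roof_vector(lm((80, 180), (120, 210), (340, 170), (300, 200)), "up")


class TestComputeAci:
    def test_three_four_five_triangle(self, square_landmarks):
        m = compute_aci(square_landmarks)
        expected = math.degrees(math.atan2(3, 4))
        assert m.right_deg == pytest.approx(expected, abs=1e-9)
        assert m.left_deg == pytest.approx(expected, abs=1e-9)
        assert round(expected, 3) == 36.870

    def test_roof_parallel_to_h_line_is_zero(self):
        m = compute_aci(lm((60, 200), (100, 200), (340, 170), (300, 200)))
        assert m.right_deg == 0.0

    def test_roof_perpendicular_to_h_line_is_ninety(self):
        m = compute_aci(lm((100, 150), (100, 200), (340, 170), (300, 200)))
        assert m.right_deg == pytest.approx(90.0, abs=1e-12)

    def test_angles_always_within_valid_range(self):
        for s in random_landmark_sets(200, seed=5):
            m = compute_aci(s)
            assert 0.0 <= m.right_deg <= 90.0
            assert 0.0 <= m.left_deg <= 90.0

    def test_matches_arccos_oracle_on_random_sets(self):
        """Independent oracle: angle between unit vectors via arccos(|h.m|)."""

        def oracle(h, m):
            h, m = h / np.linalg.norm(h), m / np.linalg.norm(m)
            return math.degrees(math.acos(min(1.0, abs(float(h @ m)))))

        for s in random_landmark_sets(1000, seed=42):
            m = compute_aci(s)
            h = hilgenreiner_vector(s)
            assert m.right_deg == pytest.approx(oracle(h, roof_vector(s, "right")), abs=1e-9)
            assert m.left_deg == pytest.approx(oracle(h, roof_vector(s, "left")), abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(
        angle=st.floats(-math.pi, math.pi),
        tx=st.floats(-200, 200),
        ty=st.floats(-200, 200),
        scale=st.floats(0.1, 10),
        idx=st.integers(0, 999),
    )
    def test_rigid_transform_invariance(self, angle, tx, ty, scale, idx):
        """Rotation + translation + uniform scaling leaves both angles unchanged."""
        base = random_landmark_sets(1, seed=idx)[0]
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        pts = scale * base.as_array() @ rot.T + np.array([tx, ty])
        before, after = compute_aci(base), compute_aci(LandmarkSet.from_array(pts))
        assert after.right_deg == pytest.approx(before.right_deg, abs=1e-9)
        assert after.left_deg == pytest.approx(before.left_deg, abs=1e-9)

    def test_mirror_symmetry_swaps_sides_exactly(self):
        for s in random_landmark_sets(50, seed=9):
            pts = s.as_array()
            mirrored = pts * np.array([-1.0, 1.0])
            ru, rd, lu, ld = mirrored
            swapped = LandmarkSet(RU=lu, RD=ld, LU=ru, LD=rd)
            a, b = compute_aci(s), compute_aci(swapped)
            assert (a.right_deg, a.left_deg) == (b.left_deg, b.right_deg)


class TestSerialization:
    def test_json_round_trip(self, square_landmarks):
        restored = LandmarkSet.from_json(square_landmarks.to_json())
        assert restored == square_landmarks

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            lm((math.nan, 0), (1, 1), (2, 2), (3, 3))


class TestClassifyDdh:
    @pytest.mark.parametrize(
        "right, left, expected",
        [
            (35, 20, ("ddh", "normal", "ddh")),
            (20, 20, ("normal", "normal", "normal")),
            (30, 10, ("ddh", "normal", "ddh")),  # boundary is inclusive
        ],
    )
    def test_threshold_rule(self, right, left, expected):
        d = classify_ddh(AcIMeasurement(right, left), threshold_deg=30)
        assert (d.right_label, d.left_label, d.overall_label) == expected
        assert d.threshold_deg == 30

    @pytest.mark.parametrize("bad", [0.0, 90.0, -5.0, 120.0])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(InvalidThresholdError):
            classify_ddh(AcIMeasurement(20, 20), threshold_deg=bad)
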