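"""Error metrics, aggregation tables and five-number summaries."""

import math

import numpy as np
import pytest

from pelvikit import (
    LandmarkErrorRecord,
    LandmarkSet,
    aci_error,
    aggregate_errors,
    compute_aci,
    five_number_summary,
    mean_pixel_error,
    pixel_error,
    rmse,
)
from pelvikit.errors import EmptyInputError, LengthMismatchError

from conftest import random_landmark_sets, three_values


def offset(lms: LandmarkSet, deltas) -> LandmarkSet:
    return LandmarkSet.from_array(lms.as_array() + np.asarray(deltas, dtype=float))


class TestPixelError:
    def test_identity_is_zero(self, square_landmarks):
        assert all(v == 0.0 for v in pixel_error(square_landmarks, square_landmarks).values())

    def test_single_three_four_offset(self, square_landmarks):
        pred = offset(square_landmarks, [(3, 4), (0, 0), (0, 0), (0, 0)])
        d = pixel_error(pred, square_landmarks)
        assert d == {"RU": 5.0, "RD": 0.0, "LU": 0.0, "LD": 0.0}
        assert mean_pixel_error(pred, square_landmarks) == 1.25

    def test_unit_offsets_mean_one(self, square_landmarks):
        pred = offset(square_landmarks, [(1, 0), (0, 1), (1, 0), (0, 1)])
        assert mean_pixel_error(pred, square_landmarks) == 1.0

    def test_matches_hypot_oracle_on_random_perturbations(self):
        rng = np.random.default_rng(17)
        for truth in random_landmark_sets(100, seed=23):
            deltas = rng.normal(0, 3, size=(4, 2))
            pred = offset(truth, deltas)
            d = pixel_error(pred, truth)
            for name, dxy in zip(("RU", "RD", "LU", "LD"), deltas):
                assert d[name] == pytest.approx(math.hypot(*dxy), abs=1e-9)

    def test_translation_invariance(self, square_landmarks):
        pred = offset(square_landmarks, [(2, 1)] * 4)
        shift = [(50, -30)] * 4
        assert pixel_error(offset(pred, shift), offset(square_landmarks, shift)) == pytest.approx(
            pixel_error(pred, square_landmarks)
        )


class TestRmse:
    def test_identity_is_zero(self, square_landmarks):
        assert rmse([square_landmarks], [square_landmarks]) == 0.0

    def test_single_landmark_offset_closed_form(self, square_landmarks):
        pred = offset(square_landmarks, [(3, 4), (0, 0), (0, 0), (0, 0)])
        assert rmse([pred], [square_landmarks]) == pytest.approx(math.sqrt(25 / 8), abs=1e-12)

    def test_constant_residuals_give_their_magnitude(self, square_landmarks):
        pred = offset(square_landmarks, np.full((4, 2), -2.5))
        assert rmse([pred], [square_landmarks]) == pytest.approx(2.5, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        truths = random_landmark_sets(50, seed=3)
        rng = np.random.default_rng(4)
        preds = [offset(t, rng.normal(0, 2, size=(4, 2))) for t in truths]
        sq = [
            (getattr(p, n).x - getattr(t, n).x) ** 2 + (getattr(p, n).y - getattr(t, n).y) ** 2
            for p, t in zip(preds, truths)
            for n in ("RU", "RD", "LU", "LD")
        ]
        assert rmse(preds, truths) == pytest.approx(math.sqrt(sum(sq) / (8 * 50)), abs=1e-9)

    def test_length_mismatch_rejected(self, square_landmarks):
        with pytest.raises(LengthMismatchError):
            rmse([square_landmarks], [])


class TestAciError:
    def test_identity_is_zero(self, square_landmarks):
        assert aci_error(square_landmarks, square_landmarks) == {"Left": 0.0, "Right": 0.0}

    def test_matches_per_side_angle_difference_oracle(self):
        rng = np.random.default_rng(31)
        for truth in random_landmark_sets(100, seed=37):
            pred = offset(truth, rng.normal(0, 4, size=(4, 2)))
            e = aci_error(pred, truth)
            a, b = compute_aci(pred), compute_aci(truth)
            assert e["Right"] == pytest.approx(abs(a.right_deg - b.right_deg), abs=1e-12)
            assert e["Left"] == pytest.approx(abs(a.left_deg - b.left_deg), abs=1e-12)
            assert e["Right"] >= 0 and e["Left"] >= 0


class TestAggregateErrors:
    def test_three_value_construction_recovers_requested_stats(self):
        v = np.array(three_values(2.582, 1.908, 2.204))
        assert np.mean(v) == pytest.approx(2.582)
        assert np.std(v, ddof=1) == pytest.approx(1.908)
        assert np.median(v) == pytest.approx(2.204)

    def test_avg_row_is_unweighted_mean_of_per_key_stats(self):
        per_landmark = {
            "RU": three_values(2.0, 1.0, 1.8),
            "RD": three_values(4.0, 2.0, 3.5),
            "LU": three_values(3.0, 1.5, 2.9),
            "LD": three_values(1.0, 0.5, 0.9),
        }
        records = [
            LandmarkErrorRecord(f"c{i}", {k: v[i] for k, v in per_landmark.items()}, {})
            for i in range(3)
        ]
        table = aggregate_errors(records, keys="landmark")
        avg = table.row("Avg")
        assert avg["mean"] == pytest.approx(2.5)
        assert avg["std"] == pytest.approx(1.25)
        assert avg["median"] == pytest.approx((1.8 + 3.5 + 2.9 + 0.9) / 4)

    def test_pooled_mode_differs_from_avg_row_when_groups_unbalanced(self):
        records = [
            LandmarkErrorRecord("a", {"RU": 0.0, "RD": 10.0, "LU": 0.0, "LD": 0.0}, {}),
            LandmarkErrorRecord("b", {"RU": 2.0, "RD": 10.0, "LU": 0.0, "LD": 0.0}, {}),
        ]
        pooled = aggregate_errors(records, keys="landmark", avg_mode="pooled").row("Avg")
        assert pooled["mean"] == pytest.approx(22 / 8)
        assert pooled["median"] == pytest.approx(0.0)

    def test_identical_records_give_zero_std(self):
        rec = LandmarkErrorRecord("a", {}, {"Left": 2.0, "Right": 3.0})
        table = aggregate_errors([rec, rec, rec], keys="side")
        assert table.row("Left") == {"mean": 2.0, "std": 0.0, "median": 2.0}
        assert table.row("Avg")["mean"] == pytest.approx(2.5)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            aggregate_errors([], keys="landmark")

    def test_csv_export_has_three_decimals(self, tmp_path):
        rec = LandmarkErrorRecord("a", {}, {"Left": 2.12345, "Right": 3.0})
        path = tmp_path / "t.csv"
        aggregate_errors([rec], keys="side").to_csv(path)
        assert "2.123" in path.read_text()


class TestFiveNumberSummary:
    def test_exact_order_statistics(self):
        s = five_number_summary([1, 2, 3, 4, 5])
        assert (s.min, s.q1, s.median, s.q3, s.max, s.iqr) == (1, 2, 3, 4, 5, 2)

    def test_matches_sorted_percentile_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(3.0, 5.0, size=200)
        s = five_number_summary(values)
        v = np.sort(values)

        def percentile(q):  # linear interpolation between closest ranks
            pos = q * (len(v) - 1)
            lo, frac = int(pos), pos - int(pos)
            return v[lo] + frac * (v[lo + 1] - v[lo]) if frac else v[lo]

        assert s.q1 == pytest.approx(percentile(0.25), abs=1e-9)
        assert s.median == pytest.approx(percentile(0.50), abs=1e-9)
        assert s.q3 == pytest.approx(percentile(0.75), abs=1e-9)

    def test_ordering_chain_and_iqr_identity(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            s = five_number_summary(rng.normal(20, 8, size=rng.integers(1, 60)))
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
            assert s.iqr == s.q3 - s.q1

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            five_number_summary([])
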