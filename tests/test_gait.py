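"""Footprint geometry: midline, stride, stance, paw angle, stride angle."""

import math

import numpy as np
import pandas as pd
import pytest

from neurophen.gait import (
    Midline,
    compute_gait_metrics,
    estimate_midline,
    paw_angle,
    stance_width,
    stride_angle,
    stride_length,
)
from neurophen.synthetic import GaitTruth, gen_footprints


def _df(rows):
    return pd.DataFrame(
        rows, columns=["paw", "step_index", "x_mm", "y_mm", "axis_angle_deg"]
    )


def _rigid(df, angle_deg, shift):
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    out = df.copy()
    x, y = df["x_mm"].to_numpy(), df["y_mm"].to_numpy()
    out["x_mm"] = c * x - s * y + shift[0]
    out["y_mm"] = s * x + c * y + shift[1]
    out["axis_angle_deg"] = df["axis_angle_deg"] + angle_deg
    return out


class TestMidline:
    def test_symmetric_prints_give_x_axis(self):
        df = gen_footprints(GaitTruth())
        m = estimate_midline(df)
        assert m.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert abs(float(np.asarray(m.point)[1])) < 1e-9

    def test_translation_equivariance(self):
        df = gen_footprints(GaitTruth())
        m0 = estimate_midline(df)
        m1 = estimate_midline(_rigid(df, 0, (5.0, 7.0)))
        assert m1.angle_deg == pytest.approx(m0.angle_deg, abs=1e-9)
        assert np.allclose(np.asarray(m1.point), np.asarray(m0.point) + [5, 7])

    def test_direction_follows_travel(self):
        df = gen_footprints(GaitTruth())
        back = df.copy()
        back["x_mm"] = -back["x_mm"]  # animal walks toward -x
        m = estimate_midline(back)
        assert abs(abs(m.angle_deg) - 180.0) < 1e-6

    def test_noisy_midline_within_two_degrees(self):
        for seed in range(20):
            df = gen_footprints(
                GaitTruth(placement_noise_sd_mm=1.0, rng_seed=seed)
            )
            assert abs(estimate_midline(df).angle_deg) < 2.0

    def test_too_few_prints_rejected(self):
        df = _df([("LF", 0, 0.0, 1.0, 0.0), ("RF", 0, 0.0, -1.0, 0.0)])
        with pytest.raises(ValueError):
            estimate_midline(df)


class TestStrideLength:
    def test_uniform_steps(self):
        df = _df(
            [("LF", i, 70.0 * i, 10.0, 0.0) for i in range(3)]
        )
        assert stride_length(df, "LF") == pytest.approx(70.0)

    def test_rotation_invariance(self):
        df = gen_footprints(GaitTruth(stride_length_mm=65.0))
        rotated = _rigid(df, 30, (3.0, -2.0))
        assert stride_length(rotated) == pytest.approx(stride_length(df), abs=1e-9)

    def test_single_print_rejected(self):
        with pytest.raises(ValueError):
            stride_length(_df([("LF", 0, 0.0, 0.0, 0.0)]))

    def test_uses_at_most_four_strides(self):
        # five prints with one aberrant final stride beyond the fourth
        rows = [("LF", i, 70.0 * i, 10.0, 0.0) for i in range(5)]
        rows.append(("LF", 5, 70.0 * 5 + 500.0, 10.0, 0.0))
        assert stride_length(_df(rows), "LF") == pytest.approx(70.0)


class TestStanceWidth:
    def test_front_pair_width(self):
        df = _df(
            [
                ("LF", 0, 0.0, 15.0, 0.0),
                ("RF", 0, 0.0, -15.0, 0.0),
                ("LH", 0, -20.0, 10.0, 0.0),
                ("RH", 0, -20.0, -10.0, 0.0),
            ]
        )
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        front, hind = stance_width(df, midline)
        assert front == pytest.approx(30.0)
        assert hind == pytest.approx(20.0)

    def test_lateral_offset_invariance(self):
        df = gen_footprints(GaitTruth())
        shifted = df.copy()
        shifted["y_mm"] += 11.0
        assert stance_width(shifted) == pytest.approx(stance_width(df), abs=1e-9)

    def test_perpendicular_mode_ignores_stagger(self):
        # staggered left/right prints: raw distance inflates, projection not
        df = _df(
            [
                ("LF", 0, 0.0, 10.0, 0.0),
                ("RF", 0, 35.0, -10.0, 0.0),
                ("LH", 0, 1.0, 14.0, 0.0),
                ("RH", 0, 2.0, -14.0, 0.0),
            ]
        )
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        front_perp, _ = stance_width(df, midline, mode="perpendicular")
        front_raw, _ = stance_width(df, midline, mode="raw")
        assert front_perp == pytest.approx(20.0)
        assert front_raw > front_perp

    def test_missing_side_rejected(self):
        df = _df([("LF", 0, 0.0, 10.0, 0.0), ("LH", 0, 0.0, 12.0, 0.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="missing a side"):
            stance_width(df, midline)


class TestPawAngle:
    def test_parallel_axis_is_zero(self):
        df = _df([("LF", 0, 0.0, 10.0, 0.0)] + [("RF", 0, 0.0, -10.0, 0.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        angles = paw_angle(df, midline)
        assert angles["LF"] == pytest.approx(0.0)
        assert angles["RF"] == pytest.approx(0.0)

    def test_out_toeing_positive_on_both_sides(self):
        df = _df(
            [("LF", 0, 0.0, 10.0, 10.0), ("RF", 0, 0.0, -10.0, -10.0)]
        )
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        angles = paw_angle(df, midline)
        assert angles["LF"] == pytest.approx(10.0)
        assert angles["RF"] == pytest.approx(10.0)

    def test_in_toeing_negative(self):
        df = _df([("LF", 0, 0.0, 10.0, -7.0), ("RF", 0, 0.0, -10.0, 7.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        angles = paw_angle(df, midline)
        assert angles["LF"] == pytest.approx(-7.0)
        assert angles["RF"] == pytest.approx(-7.0)

    def test_missing_axis_rejected(self):
        df = _df([("LF", 0, 0.0, 10.0, np.nan)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="axis"):
            paw_angle(df, midline)


class TestStrideAngle:
    def test_forty_five_degree_diagonal(self):
        # hind at (0, -10), opposite front at (20, 10): atan2(20, 20) = 45 deg
        df = _df([("RH", 0, 0.0, -10.0, 0.0), ("LF", 0, 20.0, 10.0, 0.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        assert stride_angle(df, midline) == pytest.approx(45.0)

    def test_collinear_prints_give_zero(self):
        df = _df([("RH", 0, 0.0, 0.0, 0.0), ("LF", 0, 25.0, 0.0, 0.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        assert stride_angle(df, midline) == pytest.approx(0.0)

    def test_no_pairs_rejected(self):
        df = _df([("LF", 0, 0.0, 10.0, 0.0), ("RF", 0, 1.0, -10.0, 0.0)])
        midline = Midline(point=np.zeros(2), direction=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="pairs"):
            stride_angle(df, midline)


class TestFullMetrics:
    def test_rigid_motion_invariance(self):
        df = gen_footprints(GaitTruth(paw_angle_deg=6.0))
        a = compute_gait_metrics(df)
        b = compute_gait_metrics(_rigid(df, 73.0, (12.0, -30.0)))
        assert b.stride_length_mm == pytest.approx(a.stride_length_mm, abs=1e-9)
        assert b.stance_width_front_mm == pytest.approx(a.stance_width_front_mm, abs=1e-9)
        assert b.stance_width_hind_mm == pytest.approx(a.stance_width_hind_mm, abs=1e-9)
        assert b.paw_angle_deg == pytest.approx(a.paw_angle_deg, abs=1e-9)
        assert b.stride_angle_deg == pytest.approx(a.stride_angle_deg, abs=1e-9)

    def test_n_steps_used_recorded(self):
        m = compute_gait_metrics(gen_footprints(GaitTruth(n_steps=3)))
        assert m.n_steps_used == 3
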