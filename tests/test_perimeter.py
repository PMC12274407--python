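"""Contour extraction, side selection, and the length-minus-chord statistic."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from neurophen.perimeter import (
    AmbiguousBoundaryError,
    LayerContour,
    extract_contours,
    measure_layer,
    measure_length,
    select_outer_boundary,
)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _band(shape, row0, row1):
    m = np.zeros(shape, dtype=bool)
    m[row0:row1, :] = True
    return m


class TestExtractContours:
    def test_disk_circumference_within_one_percent(self):
        mask = _disk((300, 300), (150, 150), 100)
        (contour,) = extract_contours(mask)
        assert contour.closed
        assert contour.polyline_length_px == pytest.approx(2 * np.pi * 100, rel=0.01)

    def test_border_band_yields_two_open_contours(self):
        contours = extract_contours(_band((60, 90), 20, 32))
        assert len(contours) == 2
        assert all(not c.closed for c in contours)
        for c in contours:
            # endpoints sit on the left/right image borders
            assert {round(c.points[0][1]), round(c.points[-1][1])} == {0, 89}

    def test_single_pixel_raw_trace_matches_marching_squares(self):
        # one foreground pixel -> diamond through the 4 edge midpoints
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        (contour,) = extract_contours(mask, smooth_sigma_px=0)
        assert contour.closed
        assert contour.polyline_length_px == pytest.approx(4 * np.sqrt(0.5), abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_contours(np.zeros((10, 10), dtype=bool))


class TestSelectOuterBoundary:
    def test_straight_band_reference_above_picks_top_edge(self):
        contours = extract_contours(_band((60, 90), 20, 32))
        chosen = select_outer_boundary(contours, reference_point=(5, 45))
        assert chosen.points[:, 0].mean() < 26  # the top edge

    def test_concentric_arcs_pick_outer(self, folium_mask):
        contours = extract_contours(folium_mask.mask)
        open_contours = [c for c in contours if not c.closed]
        assert len(open_contours) == 2
        # reference just above the apex of the outer arc
        rows = [c.points[:, 0].min() for c in open_contours]
        ref = (min(rows) - 50, folium_mask.mask.shape[1] / 2)
        chosen = select_outer_boundary(contours, ref)
        assert chosen.points[:, 0].min() == min(rows)

    def test_equidistant_reference_is_ambiguous(self):
        contours = extract_contours(_band((60, 90), 20, 32))
        with pytest.raises(AmbiguousBoundaryError):
            select_outer_boundary(contours, reference_point=(25.5, 45))


class TestMeasureLength:
    def test_straight_segment_measures_zero(self):
        contour = LayerContour(points=np.array([[0.0, 0.0], [0.0, 1000.0]]), closed=False)
        res = measure_length(contour, pixel_size_mm_per_px=0.01)
        assert res.polyline_length_mm == pytest.approx(10.0)
        assert res.chord_mm == pytest.approx(10.0)
        assert res.measured_length_mm == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_measures_pi_r_minus_2r(self):
        # half-disk flat side on the bottom border -> open semicircular arc
        r = 100
        yy, xx = np.mgrid[0:130, 0:280]
        mask = (yy - 129) ** 2 + (xx - 140) ** 2 <= r**2
        res = measure_layer(mask, reference_point=(0, 140), pixel_size_mm_per_px=1.0)
        assert res.measured_length_mm == pytest.approx((np.pi - 2) * r, rel=0.02)

    def test_multi_component_measures_sum(self):
        r = 60
        yy, xx = np.mgrid[0:90, 0:420]
        mask = ((yy - 89) ** 2 + (xx - 100) ** 2 <= r**2) | (
            (yy - 89) ** 2 + (xx - 310) ** 2 <= r**2
        )
        res = measure_layer(mask, reference_point=(0, 205), pixel_size_mm_per_px=1.0)
        assert res.component_count == 2
        assert res.measured_length_mm == pytest.approx(2 * (np.pi - 2) * r, rel=0.02)

    def test_nonpositive_pixel_size_rejected(self):
        contour = LayerContour(points=np.array([[0.0, 0.0], [3.0, 4.0]]), closed=False)
        with pytest.raises(ValueError):
            measure_length(contour, 0.0)

    def test_measured_length_never_negative(self, rng):
        for _ in range(5):
            mask = ndi.binary_dilation(rng.random((80, 80)) > 0.995, iterations=6)
            if not mask.any():
                continue
            try:
                res = measure_layer(
                    mask, reference_point=(0, 40), pixel_size_mm_per_px=1.0
                )
            except AmbiguousBoundaryError:
                continue
            assert res.measured_length_mm >= 0.0


class TestInvariances:
    def _elliptic_annulus(self, shape=(400, 400), center=(200, 200)):
        """Non-circular interior band, so rotation genuinely moves it."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        d2 = ((yy - center[0]) / 1.0) ** 2 + ((xx - center[1]) / 1.6) ** 2
        return (d2 <= 110**2) & (d2 >= 70**2)

    def test_rotation_changes_length_by_under_two_percent(self):
        # the reference sits at the hole center, the fixed point of the
        # rotation, so the same (inner) edge is selected in both cases
        mask = self._elliptic_annulus()
        rotated = ndi.rotate(mask.astype(float), 30, reshape=False, order=0) > 0.5
        ref = (200, 200)
        a = measure_layer(mask, ref, pixel_size_mm_per_px=1.0)
        b = measure_layer(rotated, ref, pixel_size_mm_per_px=1.0)
        assert b.measured_length_mm == pytest.approx(a.measured_length_mm, rel=0.02)

    def test_translation_changes_length_by_under_two_percent(self):
        a = measure_layer(
            self._elliptic_annulus(center=(200, 200)), (200, 200), pixel_size_mm_per_px=1.0
        )
        b = measure_layer(
            self._elliptic_annulus(center=(187.5, 204.5)), (187.5, 204.5),
            pixel_size_mm_per_px=1.0,
        )
        assert b.measured_length_mm == pytest.approx(a.measured_length_mm, rel=0.02)

    def test_upsampling_changes_length_by_under_two_percent(self):
        mask = self._elliptic_annulus()
        big = np.kron(mask, np.ones((2, 2), dtype=bool))
        a = measure_layer(mask, (200, 200), pixel_size_mm_per_px=1.0)
        b = measure_layer(big, (400, 400), pixel_size_mm_per_px=0.5)
        assert b.measured_length_mm == pytest.approx(a.measured_length_mm, rel=0.02)

    def test_folium_scene_measured_length_within_five_percent(
        self, folium_scene, folium_mask
    ):
        truth = folium_scene.truth
        res = measure_layer(
            folium_mask, truth.reference_point_px,
            pixel_size_mm_per_px=folium_scene.params.pixel_size_mm_per_px,
        )
        assert res.measured_length_mm == pytest.approx(
            truth.measured_length_mm, rel=0.05
        )
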