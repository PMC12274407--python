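"""Outer-boundary extraction and the chord-subtracted length statistic.

The layer length that normalizes Purkinje counts is the polyline length
of the granular layer's outer (Purkinje-facing) boundary minus the
straight-line distance between the boundary's start and end points, in
mm.  Contours are traced sub-pixel with marching squares on a lightly
smoothed copy of the mask: tracing the raw binary mask systematically
overestimates smooth-boundary length (staircase bias, about +6% on a
circle), while the smoothed trace is accurate to a fraction of a
percent.  Pass ``smooth_sigma_px=0`` for the exact raw-grid trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .segmentation import LayerMask

__all__ = [
    "LayerContour",
    "LengthResult",
    "AmbiguousBoundaryError",
    "extract_contours",
    "select_outer_boundary",
    "measure_length",
    "measure_layer",
]


class AmbiguousBoundaryError(ValueError):
    """Raised when boundary sides cannot be told apart by the reference."""


@dataclass
class LayerContour:
    """Ordered sub-pixel boundary points, (row, col) in pixel units."""

    points: np.ndarray
    closed: bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("contour needs at least 2 points")

    @property
    def endpoints(self) -> np.ndarray:
        """Endpoints of the boundary, (2, 2) as (row, col).

        For open contours these are the first and last vertices (which
        lie on the image border for border-clipped layers).  For closed
        contours the boundary has no border endpoints; the pair of
        vertices at maximal Euclidean separation (the diameter) is used,
        matching the start/end of a layer that wraps almost fully
        around a section.
        """
        if not self.closed:
            return np.stack([self.points[0], self.points[-1]])
        pts = self.points[:: max(1, len(self.points) // 512)]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        return np.stack([pts[i], pts[j]])

    @property
    def polyline_length_px(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass
class LengthResult:
    """Layer length statistic of one section (possibly multi-component)."""

    polyline_length_mm: float
    chord_mm: float
    measured_length_mm: float
    component_count: int

    def __post_init__(self) -> None:
        if self.measured_length_mm < -1e-9:
            raise ValueError("measured length must be non-negative")
        self.measured_length_mm = max(self.measured_length_mm, 0.0)


def _mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, LayerMask) else np.asarray(mask, dtype=bool)


def extract_contours(mask, smooth_sigma_px: float = 2.0) -> list[LayerContour]:
    """Sub-pixel iso-contours of the mask at level 0.5 (marching squares).

    One contour per connected boundary; contours that meet the image
    border are open, with endpoints on the border.
    """
    arr = _mask_array(mask)
    if not arr.any():
        raise ValueError("empty mask")
    field = arr.astype(float)
    if smooth_sigma_px > 0:
        field = ndi.gaussian_filter(field, smooth_sigma_px, mode="reflect")
    raw = measure.find_contours(field, 0.5)
    contours = []
    for pts in raw:
        closed = bool(np.allclose(pts[0], pts[-1]))
        contours.append(LayerContour(points=pts, closed=closed))
    if not contours:
        raise ValueError("mask has no traceable boundary")
    return contours


def select_outer_boundary(
    contours: list[LayerContour],
    reference_point: tuple[float, float],
    tol_px: float = 2.0,
) -> LayerContour:
    """Pick the boundary on the Purkinje-facing side of the band.

    ``reference_point`` is a (row, col) point on the Purkinje side of
    the layer (from configuration, annotation, or synthetic truth).
    Open contours (the through-going sides of a border-clipped band)
    are preferred over closed ones, and candidates are ranked by
    minimum vertex distance to the reference: for parallel band sides
    it agrees with a mean-distance ranking, and for concentric arcs
    (outer vs. inner edge of a curved layer) it separates the edges
    where the mean does not.  Candidates scoring within ``tol_px`` of
    each other are ambiguous and rejected so the caller can annotate
    explicitly.
    """
    if not contours:
        raise ValueError("no contours supplied")
    ref = np.asarray(reference_point, dtype=float)
    candidates = [c for c in contours if not c.closed] or contours
    if len(candidates) == 1:
        return candidates[0]
    scores = []
    for c in candidates:
        d = np.hypot(*(c.points - ref).T)
        scores.append(float(d.min()))
    order = np.argsort(scores)
    if scores[order[1]] - scores[order[0]] < tol_px:
        raise AmbiguousBoundaryError(
            "reference point does not separate candidate boundaries "
            f"(scores {sorted(scores)[:2]}); provide an explicit annotation"
        )
    return candidates[order[0]]


def measure_length(
    contour: LayerContour, pixel_size_mm_per_px: float
) -> LengthResult:
    """Polyline length minus the endpoint chord, converted to mm."""
    if pixel_size_mm_per_px <= 0:
        raise ValueError("pixel size must be positive")
    poly = contour.polyline_length_px * pixel_size_mm_per_px
    a, b = contour.endpoints
    chord = float(np.hypot(*(a - b))) * pixel_size_mm_per_px
    return LengthResult(
        polyline_length_mm=poly,
        chord_mm=chord,
        measured_length_mm=poly - chord,
        component_count=1,
    )


def measure_layer(
    mask,
    reference_point: tuple[float, float],
    pixel_size_mm_per_px: float | None = None,
    smooth_sigma_px: float = 2.0,
    boundary_mode: str = "outer",
) -> LengthResult:
    """Measure a (possibly multi-lobule) layer mask end to end.

    Each connected component contributes its own outer-boundary measure
    and the component measures are summed, matching a total-length-per-
    sample convention.  ``boundary_mode='outer'`` (default) measures the
    Purkinje-facing boundary selected by the reference point;
    ``'full'`` measures every boundary contour of the component before
    subtracting the selected boundary's endpoint chord.
    """
    arr = _mask_array(mask)
    if pixel_size_mm_per_px is None:
        if isinstance(mask, LayerMask):
            pixel_size_mm_per_px = mask.pixel_size_mm_per_px
        else:
            raise ValueError("pixel size required for a bare array mask")
    if boundary_mode not in ("outer", "full"):
        raise ValueError("boundary_mode must be 'outer' or 'full'")
    labels, n = ndi.label(arr)
    poly_total = chord_total = measured_total = 0.0
    measured_components = 0
    for i in range(1, n + 1):
        try:
            contours = extract_contours(labels == i, smooth_sigma_px=smooth_sigma_px)
        except ValueError:
            # specks smaller than the contour-smoothing scale carry no
            # measurable boundary; they contribute zero length
            continue
        measured_components += 1
        outer = select_outer_boundary(contours, reference_point)
        res = measure_length(outer, pixel_size_mm_per_px)
        if boundary_mode == "full":
            poly = sum(c.polyline_length_px for c in contours) * pixel_size_mm_per_px
            res = LengthResult(
                polyline_length_mm=poly,
                chord_mm=res.chord_mm,
                measured_length_mm=poly - res.chord_mm,
                component_count=1,
            )
        poly_total += res.polyline_length_mm
        chord_total += res.chord_mm
        measured_total += res.measured_length_mm
    if measured_components == 0:
        raise ValueError("mask has no traceable boundary")
    return LengthResult(
        polyline_length_mm=poly_total,
        chord_mm=chord_total,
        measured_length_mm=measured_total,
        component_count=measured_components,
    )
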