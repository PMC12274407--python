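"""Inkblot footprint-test geometry: the four runway gait measurements.

From a table of labeled paw prints (paw, step index, center in mm,
print-axis angle) the module computes, averaged over up to four steps:

* **stride length** -- mean distance between consecutive same-paw prints;
* **stance width** -- mean left/right separation of the front and of the
  hind paws, measured perpendicular to the animal's midline;
* **paw angle** -- signed rotation of each print's long axis away from
  (positive, out-toeing) or toward (negative) the midline;
* **stride angle** -- angle between the midline and the segment joining
  a hind paw to the opposite front paw of the same step cycle.

The midline is a total-least-squares line through the left/right pair
midpoints of each girdle, directed toward travel; pair midpoints lie on
the true midline identically, so all four metrics are exact on
noise-free input and invariant under rigid motions of the print set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Midline",
    "GaitMetrics",
    "estimate_midline",
    "stride_length",
    "stance_width",
    "paw_angle",
    "stride_angle",
    "compute_gait_metrics",
]

LEFT_PAWS = {"LF", "LH"}
RIGHT_PAWS = {"RF", "RH"}
FRONT_PAWS = {"LF", "RF"}
HIND_PAWS = {"LH", "RH"}
#: diagonal partner used by the stride-angle definition
OPPOSITE_FRONT = {"LH": "RF", "RH": "LF"}


@dataclass
class Midline:
    """Directed line: a point on it and a unit direction toward travel."""

    point: np.ndarray  # (x, y) mm
    direction: np.ndarray  # unit (dx, dy)

    @property
    def angle_deg(self) -> float:
        return math.degrees(math.atan2(self.direction[1], self.direction[0]))

    @property
    def left_normal(self) -> np.ndarray:
        """Unit normal pointing to the animal's left (+90 deg from travel)."""
        dx, dy = self.direction
        return np.array([-dy, dx])


@dataclass
class GaitMetrics:
    stride_length_mm: float
    stride_length_per_paw_mm: dict
    stance_width_front_mm: float
    stance_width_hind_mm: float
    paw_angle_deg: float
    paw_angle_per_paw_deg: dict
    stride_angle_deg: float
    n_steps_used: int


def _validate(prints: pd.DataFrame) -> pd.DataFrame:
    required = {"paw", "step_index", "x_mm", "y_mm"}
    missing = required - set(prints.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    bad = set(prints["paw"]) - (LEFT_PAWS | RIGHT_PAWS)
    if bad:
        raise ValueError(f"unknown paw labels: {sorted(bad)}")
    if not np.isfinite(prints[["x_mm", "y_mm"]].to_numpy()).all():
        raise ValueError("non-finite print coordinates")
    return prints.sort_values(["paw", "step_index"], kind="stable")


def _pair_left_right(
    prints: pd.DataFrame, paws: set
) -> list[tuple[pd.Series, pd.Series]]:
    """Pair left/right prints of one girdle by nearest step index."""
    sub = prints[prints["paw"].isin(paws)]
    left = sub[sub["paw"].isin(LEFT_PAWS)].sort_values("step_index")
    right = sub[sub["paw"].isin(RIGHT_PAWS)].sort_values("step_index")
    if left.empty or right.empty:
        raise ValueError(f"missing a side for girdle {sorted(paws)}")
    pairs = []
    for _, lrow in left.iterrows():
        j = (right["step_index"] - lrow["step_index"]).abs().idxmin()
        pairs.append((lrow, right.loc[j]))
    return pairs


def estimate_midline(prints: pd.DataFrame) -> Midline:
    """Total-least-squares midline through left/right pair midpoints.

    Directed so that the projection of print centers increases with
    step index (the direction of travel).
    """
    prints = _validate(prints)
    if len(prints) < 4:
        raise ValueError("need at least 4 prints to estimate a midline")
    mids = []
    for girdle in (FRONT_PAWS, HIND_PAWS):
        try:
            for lrow, rrow in _pair_left_right(prints, girdle):
                mids.append(
                    [
                        (lrow["x_mm"] + rrow["x_mm"]) / 2,
                        (lrow["y_mm"] + rrow["y_mm"]) / 2,
                    ]
                )
        except ValueError:
            continue  # one-girdle data still yields a midline
    mids = np.asarray(mids, dtype=float)
    if len(mids) < 2 or np.allclose(mids.var(axis=0), 0):
        raise ValueError("degenerate print set: midline undirectable")
    center = mids.mean(axis=0)
    _, _, vt = np.linalg.svd(mids - center)
    direction = vt[0] / np.linalg.norm(vt[0])
    # orient toward travel: centers should advance with step index
    pts = prints[["x_mm", "y_mm"]].to_numpy()
    proj = (pts - center) @ direction
    slope = np.polyfit(prints["step_index"].to_numpy(dtype=float), proj, 1)[0]
    if slope < 0:
        direction = -direction
    return Midline(point=center, direction=direction)


def stride_length(
    prints: pd.DataFrame, paw: str | None = None, max_steps: int = 4
) -> float:
    """Mean distance between consecutive same-paw prints (up to 4 strides)."""
    prints = _validate(prints)
    if paw is not None:
        prints = prints[prints["paw"] == paw]
    dists = []
    for _, sub in prints.groupby("paw"):
        pts = sub.sort_values("step_index")[["x_mm", "y_mm"]].to_numpy()
        if len(pts) < 2:
            continue
        seg = np.diff(pts, axis=0)[:max_steps]
        dists.extend(np.hypot(seg[:, 0], seg[:, 1]))
    if not dists:
        raise ValueError("fewer than 2 prints of the same paw")
    return float(np.mean(dists))


def stance_width(
    prints: pd.DataFrame,
    midline: Midline | None = None,
    mode: str = "perpendicular",
    max_steps: int = 4,
) -> tuple[float, float]:
    """Mean left/right paw separation, (front_mm, hind_mm).

    ``mode='perpendicular'`` (default) projects the left-right vector
    onto the midline normal, so staggered prints of an alternating gait
    do not inflate the width; ``mode='raw'`` uses the Euclidean
    distance between paired prints.
    """
    if mode not in ("perpendicular", "raw"):
        raise ValueError("mode must be 'perpendicular' or 'raw'")
    prints = _validate(prints)
    midline = midline or estimate_midline(prints)
    widths = []
    for girdle in (FRONT_PAWS, HIND_PAWS):
        pairs = _pair_left_right(prints, girdle)[:max_steps]
        vals = []
        for lrow, rrow in pairs:
            v = np.array(
                [lrow["x_mm"] - rrow["x_mm"], lrow["y_mm"] - rrow["y_mm"]]
            )
            if mode == "perpendicular":
                vals.append(abs(float(v @ midline.left_normal)))
            else:
                vals.append(float(np.hypot(*v)))
        widths.append(float(np.mean(vals)))
    return widths[0], widths[1]


def _signed_out_toe(axis_angle_deg: float, paw: str, midline: Midline) -> float:
    """Rotation of a print axis relative to the midline, out-toeing > 0."""
    delta = axis_angle_deg - midline.angle_deg
    delta = (delta + 180.0) % 360.0 - 180.0
    # a positive (counterclockwise) delta points toward the animal's left;
    # that is "away from the midline" for left paws, "toward" for right paws
    return delta if paw in LEFT_PAWS else -delta


def paw_angle(
    prints: pd.DataFrame,
    midline: Midline | None = None,
    max_steps: int = 4,
) -> dict:
    """Mean signed paw rotation per paw (positive = out-toeing)."""
    prints = _validate(prints)
    if "axis_angle_deg" not in prints.columns or prints["axis_angle_deg"].isna().any():
        raise ValueError("print axis angles undefined")
    midline = midline or estimate_midline(prints)
    out = {}
    for paw, sub in prints.groupby("paw"):
        angles = [
            _signed_out_toe(row["axis_angle_deg"], paw, midline)
            for _, row in sub.sort_values("step_index").head(max_steps).iterrows()
        ]
        out[paw] = float(np.mean(angles))
    return out


def stride_angle(
    prints: pd.DataFrame,
    midline: Midline | None = None,
    max_steps: int = 4,
) -> float:
    """Mean angle between the midline and hind-to-opposite-front segments."""
    prints = _validate(prints)
    midline = midline or estimate_midline(prints)
    angles = []
    for hind, front in OPPOSITE_FRONT.items():
        hsub = prints[prints["paw"] == hind].sort_values("step_index")
        fsub = prints[prints["paw"] == front].sort_values("step_index")
        if hsub.empty or fsub.empty:
            continue
        for _, hrow in hsub.head(max_steps).iterrows():
            j = (fsub["step_index"] - hrow["step_index"]).abs().idxmin()
            frow = fsub.loc[j]
            v = np.array([frow["x_mm"] - hrow["x_mm"], frow["y_mm"] - hrow["y_mm"]])
            longi = float(v @ midline.direction)
            lat = float(v @ midline.left_normal)
            angles.append(math.degrees(math.atan2(abs(lat), longi)))
    if not angles:
        raise ValueError("no hind/opposite-front pairs found")
    return float(np.mean(angles))


def compute_gait_metrics(
    prints: pd.DataFrame,
    max_steps: int = 4,
    stance_mode: str = "perpendicular",
) -> GaitMetrics:
    """All four inkblot measurements from one animal's print table."""
    prints = _validate(prints)
    midline = estimate_midline(prints)
    per_paw_stride = {}
    for paw in sorted(set(prints["paw"])):
        sub = prints[prints["paw"] == paw]
        if len(sub) >= 2:
            per_paw_stride[paw] = stride_length(sub, max_steps=max_steps)
    front, hind = stance_width(prints, midline, mode=stance_mode, max_steps=max_steps)
    per_paw_angle = paw_angle(prints, midline, max_steps=max_steps)
    n_used = min(
        max_steps, int(prints.groupby("paw")["step_index"].nunique().min())
    )
    return GaitMetrics(
        stride_length_mm=float(np.mean(list(per_paw_stride.values()))),
        stride_length_per_paw_mm=per_paw_stride,
        stance_width_front_mm=front,
        stance_width_hind_mm=hind,
        paw_angle_deg=float(np.mean(list(per_paw_angle.values()))),
        paw_angle_per_paw_deg=per_paw_angle,
        stride_angle_deg=stride_angle(prints, midline, max_steps=max_steps),
        n_steps_used=n_used,
    )
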