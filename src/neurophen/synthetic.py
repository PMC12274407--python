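"""Ground-truthed synthetic data: histology scenes, footprints, cohorts.

Every downstream stage of the package (stain separation, granular-layer
segmentation, perimeter measurement, linear density, gait metrics,
group statistics) can be validated against the analytic truth carried by
the objects generated here, with no access to real slides or animals.

The cerebellum scene emulates a calbindin/hematoxylin (H-DAB) section:
a curved, nuclei-speckled granular-layer band on a pale background, with
DAB-stained Purkinje somata strung along the band's *outer* edge.  Pixel
transmittance follows Beer-Lambert composition exactly, so color
deconvolution with the generating stain matrix recovers the
concentration fields to numerical precision (before noise).

Coordinates: image row-major, origin top-left, y increases downward.
All truth geometry is stored in mm and converted through the pixel size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stains import HDAB, RgbImage, StainMatrix, reconstruct_rgb

__all__ = [
    "StraightCenterline",
    "ArcCenterline",
    "SceneParams",
    "GroundTruth",
    "SyntheticScene",
    "GaitTruth",
    "gen_cerebellum_image",
    "gen_footprints",
    "gen_density_cohort",
    "write_scene",
]

PAWS = ("LF", "RF", "LH", "RH")


# --------------------------------------------------------------------------
# centerlines
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StraightCenterline:
    """Horizontal band centerline ``y = y0`` from ``x0`` to ``x1`` (mm)."""

    y0_mm: float
    x0_mm: float
    x1_mm: float

    def point(self, t: np.ndarray) -> np.ndarray:
        x = self.x0_mm + t * (self.x1_mm - self.x0_mm)
        return np.stack([x, np.full_like(x, self.y0_mm)], axis=-1)

    def outer_normal(self, t: np.ndarray) -> np.ndarray:
        # Purkinje side is "above" the band (smaller y).
        n = np.zeros(t.shape + (2,))
        n[..., 1] = -1.0
        return n


@dataclass(frozen=True)
class ArcCenterline:
    """Full-circle band centerline; the image border clips it open.

    Angles are measured from the downward (+y) direction so the clipped
    gap of the default scene faces the bottom image border.  The outer
    (Purkinje) side is radially outward.
    """

    center_x_mm: float
    center_y_mm: float
    radius_mm: float

    def point(self, t: np.ndarray) -> np.ndarray:
        phi = t * 2 * np.pi  # from +y, counterclockwise in (x, y-down)
        x = self.center_x_mm + self.radius_mm * np.sin(phi)
        y = self.center_y_mm + self.radius_mm * np.cos(phi)
        return np.stack([x, y], axis=-1)

    def outer_normal(self, t: np.ndarray) -> np.ndarray:
        phi = t * 2 * np.pi
        return np.stack([np.sin(phi), np.cos(phi)], axis=-1)


# --------------------------------------------------------------------------
# parameters and truth
# --------------------------------------------------------------------------


@dataclass
class SceneParams:
    """Control parameters of one synthetic cerebellum section.

    Stain OD amplitudes are in optical-density units; ``noise_sd`` is
    Gaussian noise applied in OD space (0 disables).  The same seed and
    parameters always produce a bit-identical scene.
    """

    image_size_px: tuple[int, int] = (1030, 2000)  # (rows, cols)
    pixel_size_mm_per_px: float = 0.0007
    centerline: StraightCenterline | ArcCenterline | None = None
    band_halfwidth_mm: float = 0.126  # 180 px at default pixel size
    cell_spacing_mm: float = 0.040
    cell_radius_mm: float = 0.0098
    hematoxylin_od: float = 0.8
    dab_od: float = 1.0
    nuclei_radius_mm: float = 0.0014
    nuclei_per_mm2: float = 49000.0  # ~30% areal coverage of the band
    folium_radius_px: float = 600.0  # default semicircular centerline radius
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.band_halfwidth_mm <= 0:
            raise ValueError("band_halfwidth_mm must be positive")
        if self.cell_spacing_mm <= 0:
            raise ValueError("cell_spacing_mm must be positive")
        if self.pixel_size_mm_per_px <= 0:
            raise ValueError("pixel_size_mm_per_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cell_radius_mm <= 0:
            raise ValueError("cell_radius_mm must be positive")
        if self.cell_radius_mm >= self.cell_spacing_mm / 2:
            raise ValueError(
                "cell radius larger than the gap between neighbouring somata"
            )
        if self.centerline is None:
            self.centerline = self.default_folium_centerline()
        h, w = self.image_size_px
        if 2 * self.band_halfwidth_mm / self.pixel_size_mm_per_px >= min(h, w):
            raise ValueError("band wider than image")

    def default_folium_centerline(self, radius_px: float | None = None) -> ArcCenterline:
        """Semicircular band: a half-annulus whose center sits exactly on
        the bottom border row.

        The band meets the border perpendicularly and its mirror image
        across the border completes the full annulus, so reflective
        blur boundary handling sees a continuous band and introduces no
        end artifacts; both outer-boundary endpoints lie on the border.
        """
        h, w = self.image_size_px
        px = self.pixel_size_mm_per_px
        if radius_px is None:
            radius_px = self.folium_radius_px
        return ArcCenterline(
            center_x_mm=(w / 2) * px,
            center_y_mm=(h - 1) * px,
            radius_mm=radius_px * px,
        )


@dataclass
class GroundTruth:
    """Analytic truth of one scene.

    ``outer_boundary_length_mm`` is the arc length of the band's outer
    edge between its endpoints (numeric quadrature of the offset curve);
    ``chord_mm`` the straight distance between the endpoints.  The
    measured statistic downstream is (polyline - chord), available here
    as :attr:`measured_length_mm`.
    """

    outer_boundary_length_mm: float
    chord_mm: float
    cell_count: int
    cell_centers_mm: np.ndarray  # (n, 2) as (x, y)
    endpoints_px: np.ndarray  # (2, 2) as (row, col)
    reference_point_px: tuple[float, float]  # Purkinje-side point, (row, col)

    def __post_init__(self) -> None:
        if self.chord_mm > self.outer_boundary_length_mm + 1e-9:
            raise ValueError("chord exceeds arc length")

    @property
    def true_density_cells_per_mm(self) -> float:
        return self.cell_count / self.outer_boundary_length_mm

    @property
    def measured_length_mm(self) -> float:
        """Truth analogue of the chord-subtracted length statistic."""
        return self.outer_boundary_length_mm - self.chord_mm

    def to_json(self) -> str:
        return json.dumps(
            {
                "length_mm": self.outer_boundary_length_mm,
                "chord_mm": self.chord_mm,
                "cell_count": self.cell_count,
                "cell_centers": np.asarray(self.cell_centers_mm).tolist(),
                "endpoints_px": np.asarray(self.endpoints_px).tolist(),
                "reference_point_px": list(self.reference_point_px),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            outer_boundary_length_mm=d["length_mm"],
            chord_mm=d["chord_mm"],
            cell_count=d["cell_count"],
            cell_centers_mm=np.asarray(d["cell_centers"], dtype=float),
            endpoints_px=np.asarray(d["endpoints_px"], dtype=float),
            reference_point_px=tuple(d["reference_point_px"]),
        )


@dataclass
class SyntheticScene:
    """A rendered scene plus everything needed to verify the pipeline."""

    rgb: RgbImage
    truth: GroundTruth
    hematoxylin: np.ndarray  # generating concentration fields (H x W)
    dab: np.ndarray
    band_mask: np.ndarray  # true granular-layer raster (bool)
    params: SceneParams
    stains: StainMatrix


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------


def _offset_curve_quadrature(
    centerline, halfwidth_mm: float, t0: float, t1: float, n: int = 200_000
) -> float:
    """Arc length of the outer offset curve by dense-polyline quadrature."""
    t = np.linspace(t0, t1, n)
    pts = centerline.point(t) + halfwidth_mm * centerline.outer_normal(t)
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _stamp_disks(
    img: np.ndarray, centers_px: np.ndarray, radius_px: float, value: float
) -> None:
    """Draw filled disks of ``value`` (max-composited) at integer offsets."""
    if len(centers_px) == 0:
        return
    r = int(math.ceil(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dy**2 + dx**2 <= radius_px**2
    offs = np.stack([dy[inside], dx[inside]], axis=1)  # (k, 2) as (row, col)
    cc = np.rint(centers_px).astype(int)  # (n, 2) as (row, col)
    coords = cc[:, None, :] + offs[None, :, :]
    rows = coords[..., 0].ravel()
    cols = coords[..., 1].ravel()
    keep = (rows >= 0) & (rows < img.shape[0]) & (cols >= 0) & (cols < img.shape[1])
    stamp = np.zeros_like(img)
    np.add.at(stamp, (rows[keep], cols[keep]), 1.0)
    np.maximum(img, np.minimum(stamp, 1.0) * value, out=img)


def gen_cerebellum_image(
    params: SceneParams, stains: StainMatrix = HDAB
) -> SyntheticScene:
    """Render one H-DAB cerebellum scene with analytic ground truth.

    The granular band carries hematoxylin as a dense speckle of small
    nuclei (so a small-radius white top-hat retains it while flat
    regions cancel); Purkinje somata carry DAB and sit tangent to the
    band's outer edge.  Transmittance is ``10**(-sum_s c_s * OD_s)``
    per channel on a white (I0 = 1) background.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size_px
    px = params.pixel_size_mm_per_px
    hw_mm = params.band_halfwidth_mm
    cl = params.centerline

    yy, xx = np.mgrid[0:h, 0:w]
    x_mm = xx * px
    y_mm = yy * px

    if isinstance(cl, ArcCenterline):
        r_mm = np.hypot(x_mm - cl.center_x_mm, y_mm - cl.center_y_mm)
        band = np.abs(r_mm - cl.radius_mm) <= hw_mm
        outer_r_mm = cl.radius_mm + hw_mm
        outer_r_px = outer_r_mm / px
        cy_px = cl.center_y_mm / px
        cx_px = cl.center_x_mm / px
        # half-angle (from +y) at which the outer circle crosses the
        # bottom image border; the in-image outer edge spans the rest
        cos_beta = ((h - 1) - cy_px) / outer_r_px
        if not (0 <= cos_beta < 1):
            raise ValueError("arc band must be clipped by the bottom border")
        beta = math.acos(cos_beta)
        length_mm = _offset_curve_quadrature(
            cl, hw_mm, beta / (2 * np.pi), 1 - beta / (2 * np.pi)
        )
        chord_mm = 2 * outer_r_mm * math.sin(beta)
        endpoints_px = np.array(
            [
                [h - 1, cx_px - outer_r_px * math.sin(beta)],
                [h - 1, cx_px + outer_r_px * math.sin(beta)],
            ]
        )
        reference_px = (cy_px - (outer_r_px + hw_mm / px), cx_px)
        # somata centers: tangent outside the outer edge, spaced along it
        r_cell_mm = outer_r_mm + params.cell_radius_mm
        n_slots = int(length_mm / params.cell_spacing_mm)
        arc_pos = (np.arange(n_slots) + 0.5) * params.cell_spacing_mm
        phi = beta + arc_pos / outer_r_mm  # angle from +y
        cx_cell = cl.center_x_mm - r_cell_mm * np.sin(phi)
        cy_cell = cl.center_y_mm + r_cell_mm * np.cos(phi)
        keep = cy_cell / px <= (h - 1) - params.cell_radius_mm / px
        cell_centers_mm = np.stack([cx_cell[keep], cy_cell[keep]], axis=1)
        band_area_mm2 = (
            np.pi * ((cl.radius_mm + hw_mm) ** 2 - (cl.radius_mm - hw_mm) ** 2)
        )
        n_nuclei = rng.poisson(params.nuclei_per_mm2 * band_area_mm2)
        u = rng.uniform(size=n_nuclei)
        nr = np.sqrt(
            u * ((cl.radius_mm + hw_mm) ** 2 - (cl.radius_mm - hw_mm) ** 2)
            + (cl.radius_mm - hw_mm) ** 2
        )
        nphi = rng.uniform(0, 2 * np.pi, size=n_nuclei)
        nx = cl.center_x_mm + nr * np.sin(nphi)
        ny = cl.center_y_mm + nr * np.cos(nphi)
    elif isinstance(cl, StraightCenterline):
        band = (
            (np.abs(y_mm - cl.y0_mm) <= hw_mm)
            & (x_mm >= cl.x0_mm)
            & (x_mm <= cl.x1_mm)
        )
        length_mm = _offset_curve_quadrature(cl, hw_mm, 0.0, 1.0)
        chord_mm = length_mm  # straight outer edge
        y_edge_mm = cl.y0_mm - hw_mm
        endpoints_px = np.array(
            [[y_edge_mm / px, cl.x0_mm / px], [y_edge_mm / px, cl.x1_mm / px]]
        )
        reference_px = ((y_edge_mm - 3 * hw_mm) / px, (cl.x0_mm + cl.x1_mm) / 2 / px)
        y_cell_mm = y_edge_mm - params.cell_radius_mm
        n_slots = int(length_mm / params.cell_spacing_mm)
        xs = cl.x0_mm + (np.arange(n_slots) + 0.5) * params.cell_spacing_mm
        rad_px = params.cell_radius_mm / px
        keep = (
            (xs / px >= rad_px)
            & (xs / px <= w - 1 - rad_px)
            & (y_cell_mm / px >= rad_px)
        )
        cell_centers_mm = np.stack(
            [xs[keep], np.full(keep.sum(), y_cell_mm)], axis=1
        )
        band_area_mm2 = (cl.x1_mm - cl.x0_mm) * 2 * hw_mm
        n_nuclei = rng.poisson(params.nuclei_per_mm2 * band_area_mm2)
        nx = rng.uniform(cl.x0_mm, cl.x1_mm, size=n_nuclei)
        ny = rng.uniform(cl.y0_mm - hw_mm, cl.y0_mm + hw_mm, size=n_nuclei)
    else:  # pragma: no cover - guarded by SceneParams
        raise TypeError(f"unsupported centerline type {type(cl)!r}")

    if not band.any():
        raise ValueError("band lies outside the image")

    # hematoxylin: nuclei speckle restricted to the band
    hema = np.zeros((h, w))
    nuc_px = np.stack([ny / px, nx / px], axis=1)
    _stamp_disks(hema, nuc_px, params.nuclei_radius_mm / px, params.hematoxylin_od)
    hema *= band

    # DAB: Purkinje somata
    dab = np.zeros((h, w))
    cell_px = np.stack(
        [cell_centers_mm[:, 1] / px, cell_centers_mm[:, 0] / px], axis=1
    )
    _stamp_disks(dab, cell_px, params.cell_radius_mm / px, params.dab_od)

    conc = np.zeros((h, w, 3))
    conc[:, :, 0] = hema
    conc[:, :, 1] = dab
    od = conc @ stains.matrix
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    pixels = np.clip(np.power(10.0, -od), 0.0, 1.0)

    rgb = RgbImage(pixels=pixels, pixel_size_mm_per_px=px, imax=1.0)
    truth = GroundTruth(
        outer_boundary_length_mm=length_mm,
        chord_mm=chord_mm,
        cell_count=int(len(cell_centers_mm)),
        cell_centers_mm=cell_centers_mm,
        endpoints_px=endpoints_px,
        reference_point_px=reference_px,
    )
    return SyntheticScene(
        rgb=rgb,
        truth=truth,
        hematoxylin=hema,
        dab=dab,
        band_mask=band,
        params=params,
        stains=stains,
    )


def write_scene(scene: SyntheticScene, stem: Path | str) -> tuple[Path, Path]:
    """Write an 8-bit PNG plus a JSON truth sidecar; returns both paths."""
    import imageio.v3 as iio

    stem = Path(stem)
    img_path = stem.with_suffix(".png")
    json_path = stem.with_suffix(".json")
    quantized = np.clip(
        np.rint(scene.rgb.pixels / scene.rgb.imax * 255), 0, 255
    ).astype(np.uint8)
    iio.imwrite(img_path, quantized)
    json_path.write_text(scene.truth.to_json())
    return img_path, json_path


# --------------------------------------------------------------------------
# footprints
# --------------------------------------------------------------------------


@dataclass
class GaitTruth:
    """True gait geometry of a synthetic footprint sequence.

    Out-toeing (paws rotated away from the midline) is positive.  The
    stride angle fixes the longitudinal stagger between a hind paw and
    the opposite front paw, so all four metrics are exactly recoverable
    at zero placement noise.  Defaults approximate a healthy adult
    laboratory mouse on a runway.
    """

    stride_length_mm: float = 65.0
    stance_width_front_mm: float = 20.0
    stance_width_hind_mm: float = 28.0
    paw_angle_deg: float = 8.0
    stride_angle_deg: float = 35.0
    n_steps: int = 4
    placement_noise_sd_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.placement_noise_sd_mm < 0:
            raise ValueError("placement noise sd must be non-negative")
        for name in ("stride_length_mm", "stance_width_front_mm", "stance_width_hind_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.stride_angle_deg < 90:
            raise ValueError("stride_angle_deg must lie in (0, 90)")


def gen_footprints(truth: GaitTruth) -> pd.DataFrame:
    """Generate a labeled footprint table (one row per paw print).

    Columns: ``paw`` (LF/RF/LH/RH), ``step_index``, ``x_mm`` (along the
    runway), ``y_mm`` (lateral, positive = animal's left), and
    ``axis_angle_deg`` (print long-axis direction, math convention).
    With zero placement noise the downstream gait metrics reproduce the
    truth exactly.
    """
    rng = np.random.default_rng(truth.rng_seed)
    L = truth.stride_length_mm
    wf, wh = truth.stance_width_front_mm, truth.stance_width_hind_mm
    lat = (wf + wh) / 2.0
    dx = lat / math.tan(math.radians(truth.stride_angle_deg))
    rows = []
    for i in range(truth.n_steps):
        rows.append(("LH", i, i * L, +wh / 2, +truth.paw_angle_deg))
        rows.append(("RH", i, i * L + L / 2, -wh / 2, -truth.paw_angle_deg))
        rows.append(("RF", i, i * L + dx, -wf / 2, -truth.paw_angle_deg))
        rows.append(("LF", i, i * L + L / 2 + dx, +wf / 2, +truth.paw_angle_deg))
    df = pd.DataFrame(
        rows, columns=["paw", "step_index", "x_mm", "y_mm", "axis_angle_deg"]
    )
    if truth.placement_noise_sd_mm > 0:
        noise = rng.normal(0.0, truth.placement_noise_sd_mm, size=(len(df), 2))
        df["x_mm"] += noise[:, 0]
        df["y_mm"] += noise[:, 1]
    return df


# --------------------------------------------------------------------------
# density cohorts
# --------------------------------------------------------------------------


def gen_density_cohort(
    n_per_group: int,
    mu_per_group: list[float],
    sd: float,
    seed: int,
    group_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Gaussian linear-density records, one group per supplied mean.

    Emulates the cohort structure of an ageing study (one group per
    genotype x age cell); ``sd = 0`` yields every record equal to its
    group mean.  Reproducible from ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if group_labels is None:
        group_labels = [f"group_{i + 1}" for i in range(len(mu_per_group))]
    if len(group_labels) != len(mu_per_group):
        raise ValueError("group_labels and mu_per_group length mismatch")
    rng = np.random.default_rng(seed)
    frames = []
    for label, mu in zip(group_labels, mu_per_group):
        vals = mu + rng.normal(0.0, sd, size=n_per_group) if sd > 0 else np.full(
            n_per_group, float(mu)
        )
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "sample_id": [f"{label}_{j + 1}" for j in range(n_per_group)],
                    "density_cells_per_mm": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
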