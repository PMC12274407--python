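"""Brightfield stain separation (H-DAB color deconvolution).

Brightfield chromogens absorb light, so per-channel optical density
``OD_c = -log10(I_c / I_max)`` mixes *linearly* in stain concentration
(Beer-Lambert).  Separating a hematoxylin (blue, nuclear) + DAB (brown,
calbindin) slide into per-stain concentration images is therefore a
per-pixel 3x3 linear solve against a stain matrix whose rows are the
unit-norm OD vectors of the individual stains.

The default basis is the published Ruifrok-Johansson H-DAB basis, the
de-facto standard used by QuPath/ImageJ; slide-specific vectors can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RgbImage",
    "OdImage",
    "ChannelImage",
    "StainMatrix",
    "HDAB",
    "rgb_to_od",
    "deconvolve",
    "reconstruct_rgb",
]

# Ruifrok & Johansson H-DAB optical-density vectors (R, G, B), unit-norm.
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.269, 0.568, 0.778)


@dataclass
class RgbImage:
    """An H x W x 3 brightfield image with physical pixel size.

    ``pixels`` may be any real dtype; intensities live in ``[0, imax]``
    with ``imax`` the white (blank-slide) level -- 255 for 8-bit scans,
    1.0 for float transmittance images.
    """

    pixels: np.ndarray
    pixel_size_mm_per_px: float
    imax: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RgbImage requires an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if self.imax <= 0:
            raise ValueError("imax must be positive")
        if self.pixel_size_mm_per_px <= 0:
            raise ValueError("pixel_size_mm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class OdImage:
    """Per-channel optical density, H x W x 3, non-negative."""

    od: np.ndarray
    pixel_size_mm_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


@dataclass
class ChannelImage:
    """A single per-stain concentration (or derived scalar) image."""

    values: np.ndarray
    pixel_size_mm_per_px: float
    name: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class StainMatrix:
    """Rows are unit-norm per-channel OD vectors: (stain_1, stain_2, residual).

    If only two stains are known, :meth:`from_two_stains` completes the
    third row as their normalized cross product, which spans the residual
    subspace.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("stain_1", "stain_2", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        self.matrix = m / norms[:, None]
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(
                f"stain matrix is singular or ill-conditioned (cond={cond:.3g})"
            )

    @classmethod
    def from_two_stains(
        cls,
        stain_1: tuple[float, float, float],
        stain_2: tuple[float, float, float],
        names: tuple[str, str, str] = ("stain_1", "stain_2", "residual"),
    ) -> "StainMatrix":
        a = np.asarray(stain_1, dtype=float)
        b = np.asarray(stain_2, dtype=float)
        resid = np.cross(a / np.linalg.norm(a), b / np.linalg.norm(b))
        n = np.linalg.norm(resid)
        if n == 0:
            raise ValueError("stain vectors are parallel")
        return cls(np.stack([a, b, resid / n]), names=names)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


#: Default H-DAB basis (hematoxylin, DAB, residual = their cross product).
HDAB = StainMatrix.from_two_stains(
    _HEMATOXYLIN, _DAB, names=("hematoxylin", "dab", "residual")
)


def rgb_to_od(img: RgbImage) -> OdImage:
    """Convert intensities to optical density, ``OD = -log10(I / imax)``.

    Intensities are floored at ``imax * 1e-6`` so fully black pixels map
    to a large finite OD instead of infinity.  White maps to OD 0.
    """
    if img.imax <= 0:
        raise ValueError("imax must be positive")
    eps = img.imax * 1e-6
    scaled = np.maximum(img.pixels.astype(float), eps) / img.imax
    od = -np.log10(scaled)
    return OdImage(od=od, pixel_size_mm_per_px=img.pixel_size_mm_per_px)


def deconvolve(
    od: OdImage, stains: StainMatrix = HDAB
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Unmix an OD image into per-stain concentration channels.

    Solves ``OD = c @ M`` per pixel (``M`` rows are the stain vectors)
    and clips negative concentrations to zero.  The fraction of pixels
    clipped in each channel is reported in each channel's ``name`` as a
    QC annotation and retrievable via the returned arrays.

    Returns the three channels in stain-matrix row order
    (conventionally nuclear, DAB, residual).
    """
    m = stains.matrix
    flat = od.od.reshape(-1, 3)
    conc = np.linalg.solve(m.T, flat.T).T  # c = OD @ inv(M)
    clipped_frac = (conc < -1e-12).mean(axis=0)
    conc = np.clip(conc, 0.0, None)
    h, w = od.shape
    channels = []
    for i, name in enumerate(stains.names):
        channels.append(
            ChannelImage(
                values=conc[:, i].reshape(h, w),
                pixel_size_mm_per_px=od.pixel_size_mm_per_px,
                name=f"{name} (clipped {clipped_frac[i]:.2%})",
            )
        )
    return channels[0], channels[1], channels[2]


def reconstruct_rgb(
    concentrations: np.ndarray,
    stains: StainMatrix = HDAB,
    pixel_size_mm_per_px: float = 1.0,
    imax: float = 1.0,
) -> RgbImage:
    """Forward Beer-Lambert composition: concentrations -> transmittance.

    ``concentrations`` is H x W x 3 (one plane per stain-matrix row).
    Transmittance is ``imax * 10**(-c @ M)``, the exact inverse of
    :func:`rgb_to_od` followed by :func:`deconvolve` when no clipping or
    quantization intervenes.
    """
    c = np.asarray(concentrations, dtype=float)
    od = c @ stains.matrix
    pixels = imax * np.power(10.0, -od)
    return RgbImage(
        pixels=pixels, pixel_size_mm_per_px=pixel_size_mm_per_px, imax=imax
    )
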