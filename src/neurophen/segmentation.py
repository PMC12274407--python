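"""Granular-layer segmentation from the nuclear (hematoxylin) channel.

The layer is nuclei-dense: a small-radius white top-hat keeps the
sub-structuring-element nuclei speckle and cancels flat background, a
large Gaussian blur pools the speckle into a smooth band, Otsu's
threshold binarizes it, and a slight erosion compensates the size
increase introduced by blurring.  Filter sizes are in pixels, recorded
verbatim in the provenance of every mask.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .stains import ChannelImage

__all__ = [
    "SegmentationConfig",
    "LayerMask",
    "NoLayerFoundError",
    "white_tophat",
    "gaussian_blur",
    "otsu_threshold",
    "erode",
    "segment_granular_layer",
]


class NoLayerFoundError(ValueError):
    """Raised when the filter chain leaves no candidate layer."""


@dataclass
class SegmentationConfig:
    """Pixel-unit parameters of the granular-layer filter chain."""

    tophat_radius_px: int = 5
    blur_sigma_px: float = 90.0
    erosion_radius_px: int = 10
    min_component_area_px: int = 5000

    def __post_init__(self) -> None:
        if self.tophat_radius_px <= 0 or self.blur_sigma_px <= 0:
            raise ValueError("tophat radius and blur sigma must be positive")
        if self.erosion_radius_px < 0:
            raise ValueError("erosion radius must be non-negative")
        if self.min_component_area_px < 0:
            raise ValueError("min_component_area_px must be non-negative")


@dataclass
class LayerMask:
    """Binary granular-layer mask plus the provenance that produced it."""

    mask: np.ndarray
    pixel_size_mm_per_px: float
    provenance: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ChannelImage) else np.asarray(img, dtype=float)


def white_tophat(channel, radius_px: float) -> np.ndarray:
    """Image minus its morphological opening with a disk footprint.

    Extracts bright structures smaller than the disk; the result is
    non-negative everywhere and zero on constant images.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    footprint = morphology.disk(int(round(radius_px)))
    return morphology.white_tophat(_values(channel), footprint=footprint)


def gaussian_blur(img, sigma_px: float) -> np.ndarray:
    """Separable Gaussian convolution with reflective boundaries."""
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(_values(img), sigma=sigma_px, mode="reflect")


def otsu_threshold(img, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Between-class-variance-maximizing threshold over an nbins histogram.

    Returns ``(threshold, mask)`` where the mask selects pixels strictly
    above the threshold (the bin-center value, as in common practice).
    Ties in the variance maximum are resolved to the mean of the tied
    bin centers.  A constant image has no separable classes and is
    rejected.
    """
    values = _values(img).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)
    w0 = np.cumsum(hist)
    w1 = np.cumsum(hist[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.cumsum(hist * centers) / w0
        mu1 = np.cumsum((hist * centers)[::-1])[::-1] / w1
    # between-class variance for a cut after bin k
    var_between = w0[:-1] * w1[1:] * (mu0[:-1] - mu1[1:]) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)
    best = np.flatnonzero(var_between == var_between.max())
    threshold = float(centers[best].mean())
    mask = _values(img) > threshold
    return threshold, mask


def erode(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary erosion with a disk; radius 0 is the identity.

    Out-of-image pixels are treated as foreground so the mask does not
    recede from the image border, only from its interior boundary.
    """
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    r = int(round(radius_px))
    if r == 0:
        return mask.copy()
    return ndi.binary_erosion(
        mask, structure=morphology.disk(r), border_value=1
    )


def segment_granular_layer(
    nuclear, cfg: SegmentationConfig | None = None, pixel_size_mm_per_px: float | None = None
) -> LayerMask:
    """Full chain: top-hat -> Gaussian blur -> Otsu -> erosion -> area filter.

    ``nuclear`` is the hematoxylin concentration channel.  Connected
    components smaller than ``cfg.min_component_area_px`` are dropped
    (the unattended stand-in for interactive quality control); an empty
    result raises :class:`NoLayerFoundError`.
    """
    cfg = cfg or SegmentationConfig()
    values = _values(nuclear)
    if pixel_size_mm_per_px is None:
        pixel_size_mm_per_px = (
            nuclear.pixel_size_mm_per_px if isinstance(nuclear, ChannelImage) else 1.0
        )
    th = white_tophat(values, cfg.tophat_radius_px)
    blurred = gaussian_blur(th, cfg.blur_sigma_px)
    try:
        threshold, mask = otsu_threshold(blurred)
    except ValueError as exc:
        raise NoLayerFoundError(f"no layer found: {exc}") from exc
    mask = erode(mask, cfg.erosion_radius_px)
    labels, n = ndi.label(mask)
    if n:
        areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= cfg.min_component_area_px) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise NoLayerFoundError("no layer found")
    return LayerMask(
        mask=mask,
        pixel_size_mm_per_px=pixel_size_mm_per_px,
        provenance={"config": asdict(cfg), "otsu_threshold": threshold},
    )


def qc_overlay(rgb_pixels: np.ndarray, mask: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """8-bit overlay of the mask (green) on the source image, for review."""
    base = np.asarray(rgb_pixels, dtype=float)
    if base.max() > 1.0:
        base = base / 255.0
    out = base.copy()
    green = np.array([0.0, 1.0, 0.0])
    out[mask] = (1 - alpha) * out[mask] + alpha * green
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)
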