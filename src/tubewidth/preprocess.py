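"""Pre-processing: greyscale conversion, Gaussian smoothing, contrast enhancement.

Raw tube images arrive as 8-bit RGB or greyscale rasters.  Before edge
detection they are converted to a single intensity channel, smoothed with a
normalised Gaussian kernel to suppress false edges, and contrast-enhanced so
that the tube/background transition occupies as much of the dynamic range as
possible.  Two enhancement routes are provided: plain linear contrast
stretching (which widens the range but leaves the intensity *distribution*
untouched) and histogram equalisation (which additionally concentrates
contrast where intensities cluster).  Equalisation is the default route in
the pipeline because stretching alone cannot help images that already span
the full range but have a low-variance histogram.

All intensity remaps round half-up and are applied once per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "SmoothingKernel",
    "IntensityHistogram",
    "round_half_up",
    "to_grayscale",
    "gaussian_kernel",
    "gaussian_smooth",
    "contrast_stretch",
    "equalize_histogram",
]


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, halves away from zero-wards (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def to_grayscale(img: np.ndarray, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """Collapse an 8-bit RGB image to greyscale by (weighted) channel mean.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
    weights : optional per-channel non-negative weights; the mean is
        normalised by their sum.  Useful when one colour channel carries
        most of the vessel contrast.  Default is the plain mean.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if weights is None:
        w = np.ones(3)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("weights must be 3 non-negative values with positive sum")
    grey = arr.astype(float) @ (w / w.sum())
    return np.clip(round_half_up(grey), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SmoothingKernel:
    """Discrete 2D Gaussian, normalised to unit sum.

    ``weights[radius, radius]`` is the centre tap.  The unnormalised centre
    value of the continuous kernel is 1/(2*pi*sigma^2).
    """

    sigma: float
    radius: int
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        assert abs(float(self.weights.sum()) - 1.0) < 1e-9


def gaussian_kernel(sigma: float, radius: int | None = None) -> SmoothingKernel:
    """Build the normalised Gaussian smoothing kernel.

    ``radius`` defaults to ceil(3*sigma), capturing >99% of the mass.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if radius is None:
        radius = int(np.ceil(3 * sigma))
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    w = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    return SmoothingKernel(sigma=sigma, radius=radius, weights=w / w.sum())


def gaussian_smooth(img: np.ndarray, sigma: float = 2.0, radius: int | None = None) -> np.ndarray:
    """Convolve a greyscale image with a normalised Gaussian.

    Borders use reflect-101 ("mirror") padding so no artificial dark frame
    is introduced that would later read as a false edge.
    """
    kern = gaussian_kernel(sigma, radius)
    out = ndimage.correlate(np.asarray(img, dtype=float), kern.weights, mode="mirror")
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


@dataclass
class IntensityHistogram:
    """Histogram bookkeeping for the two contrast-enhancement routes.

    Holds the per-level counts, the cumulative distribution, the observed
    extrema and the linear stretch factor 255/(max - min).
    """

    counts: np.ndarray
    total: int
    cdf: np.ndarray
    grey_min: int
    grey_max: int
    levels: int = 256

    @classmethod
    def from_image(cls, img: np.ndarray, levels: int = 256) -> "IntensityHistogram":
        flat = np.asarray(img).ravel()
        counts = np.bincount(flat, minlength=levels)[:levels]
        total = int(counts.sum())
        cdf = np.cumsum(counts) / total
        nz = np.nonzero(counts)[0]
        return cls(counts=counts, total=total, cdf=cdf,
                   grey_min=int(nz[0]), grey_max=int(nz[-1]), levels=levels)

    @property
    def stretch_factor(self) -> float:
        """E_f = 255 / (GreyMax - GreyMin); dynamic-range multiplier."""
        return 255.0 / (self.grey_max - self.grey_min)

    def equalization_map(self, out_levels: int | None = None) -> np.ndarray:
        """B_hist(n) = round((L-1) * cdf(n)), a monotone remap of the input levels.

        ``out_levels`` (L) is the number of output levels; it defaults to the
        number of input levels.
        """
        L = self.levels if out_levels is None else out_levels
        return np.clip(round_half_up((L - 1) * self.cdf), 0, L - 1).astype(np.uint8)


def contrast_stretch(img: np.ndarray) -> np.ndarray:
    """Linearly stretch intensities to span [0, 255].

    Leaves the shape of the intensity distribution unchanged; a constant
    image is returned unchanged with a warning (degenerate dynamic range).
    """
    img = np.asarray(img)
    hist = IntensityHistogram.from_image(img)
    if hist.grey_max == hist.grey_min:
        log.warning("contrast_stretch: constant image (level %d), nothing to stretch", hist.grey_min)
        return img.copy()
    # multiply before dividing so exact half-values survive in float
    scaled = (img.astype(float) - hist.grey_min) * 255.0 / (hist.grey_max - hist.grey_min)
    return np.clip(round_half_up(scaled), 0, 255).astype(np.uint8)


def equalize_histogram(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram-equalise a greyscale image onto ``levels`` output levels.

    Each intensity n maps to round((L-1) * cdf(n)); the map is total and
    monotone, and the maximum observed intensity always maps to L-1.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    img = np.asarray(img)
    hist = IntensityHistogram.from_image(img)
    return hist.equalization_map(out_levels=levels)[img]
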