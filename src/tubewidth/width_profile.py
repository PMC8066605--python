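"""Diameter measurement along the centreline via normal Bresenham rays.

At every centreline index the local tangent slope is estimated by a central
finite difference over +-4 indices (wide enough to suppress rasterisation
jitter), the normal direction is its negative reciprocal, and two opposite
rays are rasterised with Bresenham's algorithm across the silhouette until
they step onto a background pixel.  The Euclidean distance between the two
termination points is the local diameter in pixels; an optional
pixels-per-mm calibration converts it to millimetres.

Coordinates are (row, col); slopes are expressed as dy/dx with y = row and
x = col.  A vertical tangent is represented by the explicit flag
:data:`VERTICAL`, never an infinite float.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .centreline_extract import Centreline
from .errors import ParameterError, TubeWidthError
from .silhouette_fill import bresenham_line

__all__ = [
    "VERTICAL",
    "DiameterRecord",
    "DiameterProfile",
    "local_gradient",
    "cast_normal_ray",
    "diameter_at",
    "profile",
    "calibrate",
]


class _Vertical:
    """Sentinel for a vertical tangent (infinite slope)."""

    def __repr__(self) -> str:  # pragma: no cover
        return "VERTICAL"


VERTICAL = _Vertical()


def local_gradient(line: Centreline, i: int, offset: int = 4):
    """Centreline slope at index ``i`` by central finite difference.

    slope = (y[i-offset] - y[i+offset]) / (x[i-offset] - x[i+offset]);
    returns :data:`VERTICAL` when the x-denominator is zero.
    """
    if offset < 1:
        raise ParameterError(f"offset must be >= 1, got {offset}")
    n = len(line)
    if i < offset or i > n - 1 - offset:
        raise IndexError(f"index {i} within {offset} of the line ends (N={n})")
    y0, x0 = line.points[i - offset]
    y1, x1 = line.points[i + offset]
    if x0 == x1:
        return VERTICAL
    return (y0 - y1) / (x0 - x1)


def _normal_direction(slope) -> tuple[float, float]:
    """Unit (drow, dcol) vector of the normal (negative reciprocal slope)."""
    if slope is VERTICAL:  # tangent vertical -> normal horizontal
        return (0.0, 1.0)
    # tangent (dx, dy) = (1, m) -> normal (dx, dy) = (m, -1) up to sign
    v = np.array([-1.0, float(slope)])  # (drow, dcol) = (dy, dx) of normal
    return tuple(v / np.hypot(*v))


def cast_normal_ray(silhouette: np.ndarray, origin: tuple[int, int], slope, direction: int) -> tuple[int, int]:
    """Walk the normal ray from ``origin`` to the silhouette contour.

    The ray through ``origin`` perpendicular to the centreline slope is
    rasterised with Bresenham's algorithm and walked in ``direction``
    (+1/-1) until the next pixel would be background (value 0) or outside
    the image; the last foreground pixel is returned.
    """
    sil = np.asarray(silhouette)
    h, w = sil.shape
    r0, c0 = int(origin[0]), int(origin[1])
    if sil[r0, c0] == 0:
        raise TubeWidthError(f"ray origin {origin} lies outside the silhouette")
    dr, dc = _normal_direction(slope)
    reach = h + w
    far = (int(round(r0 + direction * dr * reach)), int(round(c0 + direction * dc * reach)))
    last = (r0, c0)
    for r, c in bresenham_line((r0, c0), far):
        if not (0 <= r < h and 0 <= c < w) or sil[r, c] == 0:
            break
        last = (int(r), int(c))
    return last


@dataclass(frozen=True)
class DiameterRecord:
    """One diameter measurement at a centreline index."""

    index: int
    slope: object  # float or VERTICAL
    end1: tuple[int, int]  # (row, col) of the +1-direction ray terminus
    end2: tuple[int, int]
    d_px: float
    d_mm: float | None = None


def diameter_at(silhouette: np.ndarray, line: Centreline, i: int, offset: int = 4) -> DiameterRecord:
    """Diameter at centreline index ``i``.

    The finite-difference offset shrinks symmetrically near the line ends
    down to 1; the diameter is the Euclidean distance between the two
    opposite ray termini.
    """
    n = len(line)
    off = min(offset, i, n - 1 - i)
    if off < 1:
        raise IndexError(f"index {i} too close to the line end to estimate a tangent")
    slope = local_gradient(line, i, offset=off)
    origin = tuple(line.points[i])
    e1 = cast_normal_ray(silhouette, origin, slope, +1)
    e2 = cast_normal_ray(silhouette, origin, slope, -1)
    d = float(np.hypot(e1[0] - e2[0], e1[1] - e2[1]))
    return DiameterRecord(index=i, slope=slope, end1=e1, end2=e2, d_px=d)


@dataclass
class DiameterProfile:
    """Per-index diameters along a centreline.

    ``valid_domain`` is the closed index interval that excludes ``trim``
    indices at each end, where thinning initiation makes diameters
    unreliable; summary statistics are reported both trimmed and untrimmed.
    """

    records: pd.DataFrame = field(repr=False)
    valid_domain: tuple[int, int]
    pixels_per_mm: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def diameters(self) -> np.ndarray:
        return self.records["diameter_px"].to_numpy()

    def valid(self) -> pd.DataFrame:
        lo, hi = self.valid_domain
        idx = self.records["index"]
        return self.records[(idx >= lo) & (idx <= hi)]

    def mean_diameter(self, valid_only: bool = True) -> float:
        df = self.valid() if valid_only else self.records
        return float(df["diameter_px"].mean())

    def sd_diameter(self, valid_only: bool = True) -> float:
        df = self.valid() if valid_only else self.records
        return float(df["diameter_px"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "n_indices": int(len(self.records)),
            "valid_domain": [int(v) for v in self.valid_domain],
            "mean_px": self.mean_diameter(valid_only=False),
            "sd_px": self.sd_diameter(valid_only=False),
            "mean_px_valid": self.mean_diameter(valid_only=True),
            "sd_px_valid": self.sd_diameter(valid_only=True),
            "pixels_per_mm": self.pixels_per_mm,
        }

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def profile(silhouette: np.ndarray, line: Centreline, trim: int = 75, offset: int = 4) -> DiameterProfile:
    """Measure the diameter at every computable centreline index.

    ``trim`` indices at each end are excluded from the valid domain (the
    ends oscillate where the thinning initiates on the tube's cut faces).
    """
    if trim < 0:
        raise ParameterError(f"trim must be >= 0, got {trim}")
    n = len(line)
    rows = []
    for i in range(1, n - 1):
        rec = diameter_at(silhouette, line, i, offset=offset)
        r, c = line.points[i]
        rows.append({
            "index": i, "row": int(r), "col": int(c),
            "end1_row": rec.end1[0], "end1_col": rec.end1[1],
            "end2_row": rec.end2[0], "end2_col": rec.end2[1],
            "diameter_px": rec.d_px,
        })
    records = pd.DataFrame(rows)
    lo, hi = trim, n - 1 - trim
    if lo > hi or records.empty:
        raise ParameterError(
            f"valid domain empty: trim={trim} leaves nothing of an N={n} centreline")
    return DiameterProfile(records=records, valid_domain=(lo, hi))


def calibrate(prof: DiameterProfile, pixels_per_mm: float) -> DiameterProfile:
    """Convert pixel diameters to millimetres: d_mm = d_px / pixels_per_mm."""
    if pixels_per_mm <= 0:
        raise ParameterError(f"pixels_per_mm must be positive, got {pixels_per_mm}")
    records = prof.records.copy()
    records["diameter_mm"] = records["diameter_px"] / pixels_per_mm
    return replace(prof, records=records, pixels_per_mm=pixels_per_mm)
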