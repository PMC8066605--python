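"""Edge extraction: Sobel gradients, orientation quantisation, non-maximum
suppression, double-threshold hysteresis, and component filtering.

The detector is a Canny-style chain built around a 2/3/2-weighted Sobel
variant (rather than the classical 1/2/1 weights).  Gradient orientation is
expressed as a bearing from the positive y (row) axis, clockwise, in
[0, 360).  For suppression the bearing is quantised to one of four
intercardinal directions, each naming the pair of 3x3 neighbours to compare
against.

Neighbourhood labelling: the centre pixel is P1 and P_k (k = 2..9) sits at
bearing (k - 2) * 45 degrees, i.e.

    P2 = (+1,  0)   P3 = (+1, +1)   P4 = (0, +1)   P5 = (-1, +1)
    P6 = (-1,  0)   P7 = (-1, -1)   P8 = (0, -1)   P9 = (+1, -1)

in (row, col) offsets, so opposite labels (P2/P6, P3/P7, ...) always lie on
one straight line through the centre.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DimensionError, InsufficientEdgesError, ParameterError

__all__ = [
    "SOBEL_X",
    "SOBEL_Y",
    "NEIGHBOUR_OFFSETS",
    "GradientField",
    "EdgeComponent",
    "sobel_gradients",
    "quantize_orientation",
    "nonmax_suppress",
    "hysteresis_binarize",
    "extract_components",
    "keep_longest_two",
]

# 2/3/2-weighted Sobel pair; X responds to column-wise intensity change,
# Y to row-wise change.
SOBEL_X = np.array([[-2, 0, 2],
                    [-3, 0, 3],
                    [-2, 0, 2]], dtype=float)
SOBEL_Y = SOBEL_X.T.copy()

# Classical Sobel, selectable for comparison runs.
SOBEL_X_CLASSIC = np.array([[-1, 0, 1],
                            [-2, 0, 2],
                            [-1, 0, 1]], dtype=float)
SOBEL_Y_CLASSIC = SOBEL_X_CLASSIC.T.copy()

#: P1 is the centre; P_k sits at bearing (k-2)*45 deg from the +row axis.
NEIGHBOUR_OFFSETS: dict[str, tuple[int, int]] = {
    "P1": (0, 0),
    "P2": (1, 0),
    "P3": (1, 1),
    "P4": (0, 1),
    "P5": (-1, 1),
    "P6": (-1, 0),
    "P7": (-1, -1),
    "P8": (0, -1),
    "P9": (1, -1),
}

#: Quantised bearing -> (pixel triple compared during suppression).
_ORIENTATION_TRIPLES = {
    0: ("P2", "P1", "P6"),
    45: ("P7", "P1", "P3"),
    90: ("P8", "P1", "P4"),
    135: ("P9", "P1", "P5"),
}


@dataclass
class GradientField:
    """Per-pixel Sobel responses, gradient magnitude and bearing.

    ``theta`` is measured from the positive y (row) axis, clockwise,
    in degrees within [0, 360); it is meaningful wherever magnitude > 0.
    """

    ix: np.ndarray
    iy: np.ndarray
    magnitude: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)


def sobel_gradients(img: np.ndarray, variant: str = "232") -> GradientField:
    """Compute the gradient field of a greyscale image.

    ``variant`` selects the 2/3/2 kernels (default) or ``"classic"`` 1/2/1
    Sobel for comparison.  Borders use mirror padding, so a uniform border
    region produces zero gradient rather than a frame artefact.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"expected 2D greyscale image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise DimensionError(f"image {arr.shape} smaller than the 3x3 kernel")
    if variant == "232":
        kx, ky = SOBEL_X, SOBEL_Y
    elif variant == "classic":
        kx, ky = SOBEL_X_CLASSIC, SOBEL_Y_CLASSIC
    else:
        raise ParameterError(f"unknown Sobel variant {variant!r}")
    ix = ndimage.correlate(arr, kx, mode="mirror")
    iy = ndimage.correlate(arr, ky, mode="mirror")
    magnitude = np.hypot(ix, iy)
    theta = np.degrees(np.arctan2(ix, iy)) % 360.0
    return GradientField(ix=ix, iy=iy, magnitude=magnitude, theta=theta)


def quantize_orientation(theta: float) -> tuple[int, tuple[str, str, str]]:
    """Quantise a bearing in [0, 360) to {0, 45, 90, 135} and its pixel triple.

    Boundary angles (22.5, 67.5, ...) go to the higher bucket; the map has
    period 180 since suppression only needs the undirected gradient line.
    """
    if not (0.0 <= theta < 360.0):
        raise ParameterError(f"theta must be in [0, 360), got {theta}")
    a = theta % 180.0
    if 22.5 <= a < 67.5:
        bucket = 45
    elif 67.5 <= a < 112.5:
        bucket = 90
    elif 112.5 <= a < 157.5:
        bucket = 135
    else:
        bucket = 0
    return bucket, _ORIENTATION_TRIPLES[bucket]


def _quantize_array(theta: np.ndarray) -> np.ndarray:
    a = np.mod(theta, 180.0)
    bucket = np.zeros(a.shape, dtype=np.int16)
    bucket[(a >= 22.5) & (a < 67.5)] = 45
    bucket[(a >= 67.5) & (a < 112.5)] = 90
    bucket[(a >= 112.5) & (a < 157.5)] = 135
    return bucket


def _shift(arr: np.ndarray, dr: int, dc: int, fill: float = 0.0) -> np.ndarray:
    """View of ``arr`` displaced by (dr, dc); vacated cells take ``fill``."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs, re = max(dr, 0), h + min(dr, 0)
    cs, ce = max(dc, 0), w + min(dc, 0)
    out[rs:re, cs:ce] = arr[rs - dr:re - dr, cs - dc:ce - dc]
    return out


def nonmax_suppress(field: GradientField) -> np.ndarray:
    """Zero every gradient pixel not a local maximum along its bearing.

    A pixel survives iff its magnitude is >= both neighbours named by its
    orientation triple (>= so ridge plateaus are not erased); neighbours
    outside the grid count as zero.
    """
    mag = field.magnitude
    bucket = _quantize_array(field.theta)
    keep = np.zeros(mag.shape, dtype=bool)
    for angle, (pa, _, pb) in _ORIENTATION_TRIPLES.items():
        sel = bucket == angle
        da, db = NEIGHBOUR_OFFSETS[pa], NEIGHBOUR_OFFSETS[pb]
        na = _shift(mag, -da[0], -da[1])  # value at pixel + offset
        nb = _shift(mag, -db[0], -db[1])
        keep |= sel & (mag >= na) & (mag >= nb)
    return np.where(keep, mag, 0.0)


def hysteresis_binarize(suppressed: np.ndarray, z1: float, z2: float) -> np.ndarray:
    """Double-threshold the suppressed magnitude map into a binary edge image.

    Pixels above z2 are edges outright; pixels below z1 never are; pixels in
    [z1, z2] are kept only when an 8-connected chain of non-zero pixels links
    them to some above-z2 pixel.  The chain scan is a deterministic breadth-
    first traversal (connectivity does not depend on visit order).
    """
    if not (0 <= z1 < z2):
        raise ParameterError(f"need 0 <= z1 < z2, got z1={z1}, z2={z2}")
    s = np.asarray(suppressed, dtype=float)
    strong = s > z2
    nonzero = s > 0
    reached = strong.copy()
    queue: deque[tuple[int, int]] = deque(zip(*np.nonzero(strong)))
    h, w = s.shape
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and nonzero[rr, cc] and not reached[rr, cc]:
                    reached[rr, cc] = True
                    queue.append((rr, cc))
    weak = (s >= z1) & ~strong & nonzero
    return (strong | (weak & reached)).astype(np.uint8)


@dataclass
class EdgeComponent:
    """One 8-connected set of edge pixels."""

    pixels: np.ndarray  # (n, 2) int array of (row, col), row-major sorted
    @property
    def length(self) -> int:
        return len(self.pixels)


def extract_components(edges: np.ndarray) -> list[EdgeComponent]:
    """List the 8-connected components of an edge image.

    Sorted by pixel count descending; ties broken by the smallest row-major
    starting coordinate so the order is deterministic.
    """
    e = np.asarray(edges) != 0
    labels, n = ndimage.label(e, structure=np.ones((3, 3), dtype=int))
    comps = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        comps.append(EdgeComponent(pixels=np.column_stack([rr, cc])))
    comps.sort(key=lambda c: (-c.length, int(c.pixels[0, 0]), int(c.pixels[0, 1])))
    return comps


def _group_into_walls(components: list[EdgeComponent], shape: tuple[int, int]) -> list[list[int]]:
    """Group edge components that belong to one wall.

    Suppression can sever a wall's ridge over a few pixels (typically where
    it grazes the image border), so components within ~6 px of each other
    are one wall.  Returns lists of component indices, one list per wall.
    """
    img = np.zeros(shape, dtype=bool)
    for comp in components:
        img[comp.pixels[:, 0], comp.pixels[:, 1]] = True
    bridged = ndimage.binary_dilation(img, structure=np.ones((3, 3), dtype=bool),
                                      iterations=3)
    labels, n = ndimage.label(bridged, structure=np.ones((3, 3), dtype=int))
    walls: dict[int, list[int]] = {}
    for i, comp in enumerate(components):
        lab = int(labels[comp.pixels[0, 0], comp.pixels[0, 1]])
        walls.setdefault(lab, []).append(i)
    return list(walls.values())


def keep_longest_two(
    components: list[EdgeComponent],
    shape: tuple[int, int],
    manual_indices: tuple[int, int] | None = None,
) -> np.ndarray:
    """Binary image containing only the tube's two bounding walls.

    Components are first grouped into walls (short suppression breaks within
    a wall do not count as separate edges); the two walls with the most
    pixels are kept — the tube's bounding edges are assumed to be the most
    extended structures in the frame.  ``manual_indices`` overrides the
    automatic choice with explicit component indices.
    """
    if manual_indices is not None:
        chosen = [components[i] for i in manual_indices]
    else:
        if len(components) < 2:
            raise InsufficientEdgesError(
                f"found {len(components)} edge component(s); need 2. "
                "Lower the hysteresis thresholds (z1_frac/z2_frac) or use the manual override."
            )
        walls = _group_into_walls(components, shape)
        if len(walls) < 2:
            raise InsufficientEdgesError(
                "all edge components group into a single wall; need 2. "
                "Lower the hysteresis thresholds (z1_frac/z2_frac) or use the manual override."
            )
        walls.sort(key=lambda idxs: (-sum(components[i].length for i in idxs),
                                     min(idxs)))
        chosen = [components[i] for wall in walls[:2] for i in wall]
    out = np.zeros(shape, dtype=np.uint8)
    for comp in chosen:
        out[comp.pixels[:, 0], comp.pixels[:, 1]] = 1
    return out
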