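"""Synthetic control-image generation with analytic ground truth.

Renders the validation phantoms every stage of the pipeline is checked
against, so nothing ever needs downloading:

* ``straight`` — a band of constant perpendicular width crossing the whole
  frame at a given incline (the 100-px-wide, 10-degree tubes).
* ``arc`` — a quarter annulus of given outer radius and radial width,
  centred on the frame's top-left corner (a 500-px outer radius with 100-px
  width exactly spans a 500x500 frame corner to corner).
* ``varying`` — a horizontal tube whose width varies along its axis by an
  arbitrary function, for parameter-recovery checks.

Renderings are maximal-contrast (255/0) with no anti-aliasing; ``negative``
polarity is the exact intensity complement of ``positive``.  Each image is
returned with a per-arclength ground-truth width table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["TubeSpec", "GapSpec", "NoiseSpec", "make_control_image",
           "control_image", "degrade", "rescale_fixture", "write_fixture"]


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of one synthetic tube phantom.

    ``width`` is the true perpendicular (straight) or radial (arc) width in
    pixels; ``angle`` the incline in degrees from horizontal (straight
    only); ``outer_radius`` the annulus outer radius in pixels (arc only);
    ``frame`` the square image side; ``polarity`` whether the tube is
    bright on dark ("positive") or its complement.
    """

    kind: str  # straight | arc | varying
    width: float = 100.0
    angle: float = 10.0
    outer_radius: float = 500.0
    frame: int = 500
    polarity: str = "positive"
    width_function: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.kind not in ("straight", "arc", "varying"):
            raise ParameterError(f"unknown tube kind {self.kind!r}")
        if self.width <= 0:
            raise ParameterError("width must be positive")
        if self.frame < 16:
            raise ParameterError("frame too small to contain a tube")
        if self.kind == "arc" and self.outer_radius <= self.width:
            raise ParameterError("outer_radius must exceed width")
        if self.polarity not in ("positive", "negative"):
            raise ParameterError(f"polarity must be positive|negative, got {self.polarity!r}")


def _render_straight(spec: TubeSpec) -> tuple[np.ndarray, pd.DataFrame]:
    n = spec.frame
    alpha = np.radians(spec.angle)
    cr = cc = (n - 1) / 2.0  # half-integer centre for even frames
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    # signed perpendicular distance from the axis row = cr + tan(a)*(col - cc)
    perp = ((rows - cr) - np.tan(alpha) * (cols - cc)) * np.cos(alpha)
    fg = np.abs(perp) <= spec.width / 2.0
    length = int(np.ceil(n / max(abs(np.cos(alpha)), abs(np.sin(alpha)))))
    gt = pd.DataFrame({"arclength_index": np.arange(length),
                       "true_width_px": np.full(length, float(spec.width))})
    return fg, gt


def _render_arc(spec: TubeSpec) -> tuple[np.ndarray, pd.DataFrame]:
    n = spec.frame
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    r = np.hypot(rows, cols)  # annulus centred on the top-left corner pixel
    fg = (r >= spec.outer_radius - spec.width) & (r <= spec.outer_radius)
    r_mid = spec.outer_radius - spec.width / 2.0
    length = int(np.ceil(r_mid * np.pi / 2.0))
    gt = pd.DataFrame({"arclength_index": np.arange(length),
                       "true_width_px": np.full(length, float(spec.width))})
    return fg, gt


def _render_varying(spec: TubeSpec) -> tuple[np.ndarray, pd.DataFrame]:
    n = spec.frame
    if spec.width_function is None:
        raise ParameterError("varying tube requires a width_function")
    cols = np.arange(n, dtype=float)
    w = np.asarray(spec.width_function(cols), dtype=float)
    if np.any(w <= 0) or np.any(w >= n):
        raise ParameterError("width_function must stay within (0, frame)")
    rows = np.arange(n, dtype=float)[:, None]
    cr = (n - 1) / 2.0
    fg = np.abs(rows - cr) <= w[None, :] / 2.0
    gt = pd.DataFrame({"arclength_index": np.arange(n), "true_width_px": w})
    return fg, gt


def make_control_image(spec: TubeSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a tube phantom and its ground-truth width table.

    Returns ``(image, gt)`` where ``image`` is a uint8 (frame, frame) array
    with values {0, 255} and ``gt`` has columns ``arclength_index`` and
    ``true_width_px`` sampled along the analytic centreline.
    """
    render = {"straight": _render_straight, "arc": _render_arc,
              "varying": _render_varying}[spec.kind]
    fg, gt = render(spec)
    img = np.where(fg, 255, 0).astype(np.uint8)
    if spec.polarity == "negative":
        img = (255 - img).astype(np.uint8)
    return img, gt


#: The four standard validation phantoms: straight 100-px band at 10 deg
#: (A positive, B negative) and 100-px-wide quarter annulus of outer radius
#: 500 px (C positive, D negative), all in a 500x500 frame.
_CONTROL_SPECS = {
    "A": TubeSpec(kind="straight", width=100, angle=10, frame=500, polarity="positive"),
    "B": TubeSpec(kind="straight", width=100, angle=10, frame=500, polarity="negative"),
    "C": TubeSpec(kind="arc", width=100, outer_radius=500, frame=500, polarity="positive"),
    "D": TubeSpec(kind="arc", width=100, outer_radius=500, frame=500, polarity="negative"),
}


def control_image(name: str) -> tuple[np.ndarray, pd.DataFrame, TubeSpec]:
    """The standard control image A, B, C or D with its ground truth."""
    try:
        spec = _CONTROL_SPECS[name.upper()]
    except KeyError:
        raise ParameterError(f"control image must be one of A, B, C, D; got {name!r}") from None
    img, gt = make_control_image(spec)
    return img, gt, spec


@dataclass(frozen=True)
class GapSpec:
    """Edge-gap model: ``count`` gaps with geometric(p) lengths (median 1 px
    at the default p=0.5)."""

    count: int = 50
    geom_p: float = 0.5


@dataclass(frozen=True)
class NoiseSpec:
    """Additive intensity degradation: Gaussian noise and a linear
    background gradient of total amplitude ``gradient`` across the frame."""

    sigma: float = 0.0
    gradient: float = 0.0


def degrade(img: np.ndarray, gap_spec: GapSpec | None = None,
            noise_spec: NoiseSpec | None = None, seed: int = 0) -> np.ndarray:
    """Degrade a fixture image deterministically under a seed.

    For binary edge images, ``gap_spec`` punches ``count`` gaps at random
    edge pixels; each gap removes a geometric-length run walked along the
    edge.  For greyscale images, ``noise_spec`` adds Gaussian noise and/or
    a background intensity ramp.  With neither spec this is the identity.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(img).copy()
    if gap_spec is not None and gap_spec.count > 0:
        for _ in range(gap_spec.count):
            edge_px = np.argwhere(out != 0)
            if len(edge_px) == 0:
                break
            start = tuple(edge_px[rng.integers(len(edge_px))])
            length = int(rng.geometric(gap_spec.geom_p))
            # walk along the edge removing `length` connected pixels
            cur = start
            for _ in range(length):
                out[cur] = 0
                nbrs = [(cur[0] + dr, cur[1] + dc)
                        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr, dc) != (0, 0)
                        and 0 <= cur[0] + dr < out.shape[0]
                        and 0 <= cur[1] + dc < out.shape[1]
                        and out[cur[0] + dr, cur[1] + dc] != 0]
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))]
    if noise_spec is not None and (noise_spec.sigma > 0 or noise_spec.gradient != 0):
        f = out.astype(float)
        if noise_spec.gradient != 0:
            ramp = np.linspace(0, noise_spec.gradient, out.shape[1])
            f = f + ramp[None, :]
        if noise_spec.sigma > 0:
            f = f + rng.normal(0, noise_spec.sigma, out.shape)
        out = np.clip(np.floor(f + 0.5), 0, 255).astype(np.uint8)
    return out


def rescale_fixture(spec: TubeSpec, target_frame: int) -> tuple[np.ndarray, pd.DataFrame, TubeSpec]:
    """Re-render a phantom with all lengths scaled by target_frame/frame.

    The geometry is re-rendered at the new scale (width and radius scale
    proportionally) rather than pixel-resampled, so no interpolation
    artefacts are introduced.
    """
    if target_frame < 100:
        raise ParameterError(f"target_frame must be >= 100, got {target_frame}")
    k = target_frame / spec.frame
    scaled = TubeSpec(kind=spec.kind, width=spec.width * k, angle=spec.angle,
                      outer_radius=spec.outer_radius * k, frame=target_frame,
                      polarity=spec.polarity,
                      width_function=(None if spec.width_function is None else
                                      (lambda s, f=spec.width_function, k=k: k * np.asarray(f(np.asarray(s) / k)))))
    img, gt = make_control_image(scaled)
    return img, gt, scaled


def write_fixture(directory, name: str, img: np.ndarray, gt: pd.DataFrame,
                  spec: TubeSpec, seed: int | None = None) -> None:
    """Write a fixture set: PNG image, ground-truth CSV and manifest JSON."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{name}.png", img)
    gt.to_csv(directory / f"{name}_ground_truth.csv", index=False)
    meta = {k: v for k, v in asdict(spec).items() if k != "width_function"}
    meta["has_width_function"] = spec.width_function is not None
    meta["seed"] = seed
    (directory / f"{name}_manifest.json").write_text(json.dumps(meta, indent=2))
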