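"""End-to-end pipeline: image in, diameter profile and artefact bundle out.

Stage order: greyscale -> contrast enhancement (equalisation by default,
linear stretch otherwise) -> Gaussian smooth -> Sobel gradients ->
non-maximum suppression -> hysteresis binarisation -> component filtering
(two longest edges) -> silhouette fill -> Zhang-Suen thinning -> secondary
thinning -> centreline ordering -> normal-ray width profile -> optional
millimetre calibration.  Every stage is timed and logged; intermediate
images can be dumped as PNGs for inspection.

The default path contains no randomness, so identical input, configuration
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import preprocess, edge_detect, silhouette_fill, centreline_extract, width_profile
from .centreline_extract import Centreline
from .errors import ParameterError, TubeWidthError
from .width_profile import DiameterProfile

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_image"]


@dataclass
class PipelineConfig:
    """Every free parameter of the pipeline in one place.

    ``z1_frac``/``z2_frac`` are the hysteresis thresholds as fractions of
    the maximum suppressed gradient magnitude (scale-invariant across the
    8-bit pipeline); ``gradient_offset`` is the finite-difference half-width
    for the centreline tangent; ``end_trim`` the number of indices excluded
    at each centreline end.
    """

    sigma: float = 2.0
    kernel_radius: int | None = None  # default: ceil(3*sigma)
    use_equalization: bool = True
    z1_frac: float = 0.08
    z2_frac: float = 0.20
    sobel_variant: str = "232"
    gradient_offset: int = 4
    end_trim: int = 75
    fill_combination: str = "intersection"
    pixels_per_mm: float | None = None
    colour_weights: tuple[float, float, float] | None = None
    manual_edge_indices: tuple[int, int] | None = None
    seed: int = 0
    debug_dir: str | None = None

    def __post_init__(self):
        if not (0 <= self.z1_frac < self.z2_frac <= 1):
            raise ParameterError(
                f"need 0 <= z1_frac < z2_frac <= 1, got {self.z1_frac}, {self.z2_frac}")
        if self.gradient_offset < 1:
            raise ParameterError("gradient_offset must be >= 1")
        if self.end_trim < 0:
            raise ParameterError("end_trim must be >= 0")

    def echo(self) -> dict:
        d = asdict(self)
        d["colour_weights"] = None if self.colour_weights is None else list(self.colour_weights)
        d["manual_edge_indices"] = (None if self.manual_edge_indices is None
                                    else list(self.manual_edge_indices))
        return d


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    profile: DiameterProfile
    centreline: Centreline = field(repr=False)
    silhouette: np.ndarray = field(repr=False)
    edges: np.ndarray = field(repr=False)
    grey: np.ndarray = field(repr=False)
    summary: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def write(self, prefix) -> None:
        """Write the profile CSV, summary JSON and overlay PNG."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.profile.to_csv(f"{prefix}_profile.csv")
        Path(f"{prefix}_summary.json").write_text(json.dumps(self.summary, indent=2))
        _write_overlay(f"{prefix}_overlay.png", self.grey, self.silhouette,
                       self.centreline, self.profile)


def load_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF/JPEG as RGB or greyscale array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _dump(debug_dir, name, arr):
    if debug_dir is None:
        return
    import imageio.v3 as iio

    d = Path(debug_dir)
    d.mkdir(parents=True, exist_ok=True)
    a = np.asarray(arr)
    if a.dtype != np.uint8:
        amax = a.max()
        a = (255 * a / amax).astype(np.uint8) if amax > 0 else np.zeros_like(a, dtype=np.uint8)
    iio.imwrite(d / f"{name}.png", a)


def _write_overlay(path, grey, silhouette, line, prof, ray_every: int = 25) -> None:
    """Centreline (red), silhouette tint (blue) and sample normals (green)
    drawn over the greyscale input."""
    import imageio.v3 as iio
    from .silhouette_fill import bresenham_line

    rgb = np.stack([grey] * 3, axis=-1).astype(np.uint8)
    sil = silhouette != 0
    rgb[sil, 2] = np.minimum(255, rgb[sil, 2].astype(int) + 60).astype(np.uint8)
    recs = prof.records
    for _, rec in recs.iloc[::ray_every].iterrows():
        for r, c in bresenham_line((rec["end1_row"], rec["end1_col"]),
                                   (rec["end2_row"], rec["end2_col"])):
            if 0 <= r < rgb.shape[0] and 0 <= c < rgb.shape[1]:
                rgb[r, c] = (0, 200, 0)
    rgb[line.rows, line.cols] = (255, 0, 0)
    iio.imwrite(path, rgb)


def run_pipeline(image, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full diameter-estimation pipeline on an image or image path.

    Returns a :class:`PipelineResult`; stage failures carry the stage name
    and a remediation hint where one exists.
    """
    cfg = config or PipelineConfig()
    if isinstance(image, (str, Path)):
        image = load_image(image)
    image = np.asarray(image)
    timings: dict[str, float] = {}

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except TubeWidthError as exc:
            raise TubeWidthError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %-20s %.3f s", name, timings[name])
        return out

    if image.ndim == 3:
        grey = stage("to_grayscale", preprocess.to_grayscale, image, cfg.colour_weights)
    else:
        grey = image.astype(np.uint8)
    _dump(cfg.debug_dir, "01_grey", grey)

    # Enhancement precedes smoothing: equalising after the Gaussian pass
    # redistributes the transition-ramp levels of a strongly bimodal image
    # and displaces the gradient maximum away from the physical boundary,
    # biasing every diameter; on the enhanced image the ramp produced by
    # smoothing is symmetric about the true edge.
    if cfg.use_equalization:
        enhanced = stage("equalize_histogram", preprocess.equalize_histogram, grey)
    else:
        enhanced = stage("contrast_stretch", preprocess.contrast_stretch, grey)
    _dump(cfg.debug_dir, "02_enhanced", enhanced)

    smooth = stage("gaussian_smooth", preprocess.gaussian_smooth, enhanced,
                   cfg.sigma, cfg.kernel_radius)
    _dump(cfg.debug_dir, "03_smooth", smooth)

    field_ = stage("sobel_gradients", edge_detect.sobel_gradients, smooth, cfg.sobel_variant)
    _dump(cfg.debug_dir, "04_magnitude", field_.magnitude)

    suppressed = stage("nonmax_suppress", edge_detect.nonmax_suppress, field_)
    _dump(cfg.debug_dir, "05_suppressed", suppressed)

    smax = float(suppressed.max())
    binary = stage("hysteresis_binarize", edge_detect.hysteresis_binarize,
                   suppressed, cfg.z1_frac * smax, cfg.z2_frac * smax)
    _dump(cfg.debug_dir, "06_binary_edges", binary * 255)

    components = stage("extract_components", edge_detect.extract_components, binary)
    edges = stage("keep_longest_two", edge_detect.keep_longest_two,
                  components, binary.shape, cfg.manual_edge_indices)
    _dump(cfg.debug_dir, "07_two_edges", edges * 255)

    silhouette = stage("fill_silhouette", silhouette_fill.fill_silhouette,
                       edges, cfg.fill_combination)
    _dump(cfg.debug_dir, "08_silhouette", silhouette * 255)

    skeleton = stage("zhang_suen_thin", centreline_extract.zhang_suen_thin, silhouette)
    skeleton = stage("secondary_thin", centreline_extract.secondary_thin, skeleton)
    _dump(cfg.debug_dir, "09_skeleton", skeleton * 255)

    line = stage("order_centreline", centreline_extract.order_centreline, skeleton)

    prof = stage("profile", width_profile.profile, silhouette, line,
                 cfg.end_trim, cfg.gradient_offset)
    if cfg.pixels_per_mm is not None:
        prof = stage("calibrate", width_profile.calibrate, prof, cfg.pixels_per_mm)

    summary = {
        "diameter": prof.summary(),
        "config": cfg.echo(),
        "n_centreline_points": int(len(line)),
        "silhouette_area_px": int(silhouette.sum()),
    }
    return PipelineResult(profile=prof, centreline=line, silhouette=silhouette,
                          edges=edges, grey=grey, summary=summary, timings=timings)
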