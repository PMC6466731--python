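"""Densitometry for immunofluorescence sections and immunoblots.

Immunofluorescence: the red-channel signal of each retinal layer (OPL, INL,
IPL, GCL) is summed over a hand-drawn polygon, ten images per retina are
summed to represent the whole retina, and each treated retina is normalized
to its control partner mounted on the same slide (same reaction, same
imaging session), removing slide-level gain.  Group inference on the raw
totals uses a paired t test.

Immunoblots: band optical density is the integrated lane profile minus a
background estimate (median of a user-designated background strip times the
band width), and each target band is expressed relative to the beta-actin
band of the same lane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .stats import StatResult, paired_compare

__all__ = [
    "LayerMeasurement",
    "PairedRetinaQuant",
    "BlotBand",
    "LAYERS",
    "layer_sum",
    "retina_total",
    "pair_normalize",
    "blot_ratio",
    "synthetic_layered_image",
]

LAYERS = ("OPL", "INL", "IPL", "GCL")
IMAGES_PER_RETINA = 10


@dataclass(frozen=True)
class LayerMeasurement:
    retina_id: str
    group: str
    layer: str
    image_index: int
    red_sum: float

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if not 1 <= self.image_index:
            raise ValueError("image_index starts at 1")
        if self.red_sum < 0:
            raise ValueError("red_sum must be >= 0")


@dataclass(frozen=True)
class PairedRetinaQuant:
    """Whole-retina totals of one control/treated pair from the same slide."""

    slide_id: str
    ctr_total: float
    vpa_total: float

    @property
    def ratio(self) -> float:
        if self.ctr_total <= 0:
            return math.nan
        return self.vpa_total / self.ctr_total


@dataclass(frozen=True)
class BlotBand:
    lane_id: str
    target_od: float
    actin_od: float

    def __post_init__(self) -> None:
        if self.actin_od <= 0:
            raise ValueError("actin OD must be > 0 for normalization")
        if self.target_od < 0:
            raise ValueError("ODs must be >= 0 after background subtraction")

    @property
    def ratio_od(self) -> float:
        return self.target_od / self.actin_od


def layer_sum(image: np.ndarray, polygon: Sequence[Sequence[float]]) -> float:
    """Sum of pixel values whose centers fall inside the polygon.

    ``polygon`` is a list of (x, y) vertices in pixel coordinates (0-based,
    x right, y down); pixel centers sit at integer coordinates.  Centers
    exactly on the boundary are resolved with the top/left rule (a center
    on a shared edge belongs to the polygon to its right/below), so sums
    over edge-sharing polygons are additive.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D single-channel array")
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    h, w = image.shape
    if verts[:, 0].min() < -0.5 or verts[:, 0].max() > w - 0.5 or verts[:, 1].min() < -0.5 or verts[:, 1].max() > h - 0.5:
        raise ValueError("polygon extends outside the image bounds")
    x0, x1 = int(np.floor(verts[:, 0].min())), int(np.ceil(verts[:, 0].max()))
    y0, y1 = int(np.floor(verts[:, 1].min())), int(np.ceil(verts[:, 1].max()))
    xs = np.arange(max(x0, 0), min(x1, w - 1) + 1)
    ys = np.arange(max(y0, 0), min(y1, h - 1) + 1)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("polygon encloses no pixel centers")
    gx, gy = np.meshgrid(xs, ys)
    # The tiny positive offset implements the top/left boundary rule.
    pts = np.column_stack([gx.ravel() + 1e-7, gy.ravel() + 1e-7])
    inside = MplPath(verts).contains_points(pts)
    if not np.any(inside):
        raise ValueError("polygon encloses no pixel centers")
    return float(image[gy.ravel()[inside], gx.ravel()[inside]].sum())


def retina_total(measurements: Sequence[LayerMeasurement], min_images: int = IMAGES_PER_RETINA) -> tuple:
    """Whole-retina total for one layer: sum over the per-image sums.

    Returns ``(total, flags)``; fewer than ``min_images`` images yields a
    warning and the ``"incomplete_image_set"`` flag rather than an error.
    """
    if not measurements:
        raise ValueError("no measurements")
    retinas = {m.retina_id for m in measurements}
    layers = {m.layer for m in measurements}
    if len(retinas) != 1 or len(layers) != 1:
        raise ValueError("measurements must come from a single retina and layer")
    indices = [m.image_index for m in measurements]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate image_index")
    flags = ()
    if len(measurements) < min_images:
        warnings.warn(
            f"only {len(measurements)} images for retina {next(iter(retinas))}; {min_images} expected",
            stacklevel=2,
        )
        flags = ("incomplete_image_set",)
    return float(sum(m.red_sum for m in measurements)), flags


def pair_normalize(pairs: Sequence[PairedRetinaQuant]) -> tuple:
    """Per-pair treated/control ratios with mean, SEM and a paired t test.

    Pairs with a non-positive control total are excluded (flagged), since
    the ratio is undefined.  Returns ``(mean_ratio, sem, stat_result)``.
    """
    usable = [p for p in pairs if p.ctr_total > 0]
    if len(usable) < 3:
        raise ValueError("need at least 3 usable pairs")
    ratios = np.array([p.ratio for p in usable])
    mean = float(np.mean(ratios))
    sem = float(np.std(ratios, ddof=1) / math.sqrt(ratios.size))
    result: StatResult = paired_compare([p.vpa_total for p in usable], [p.ctr_total for p in usable])
    return mean, sem, result


def blot_ratio(
    lane_id: str,
    target_profile: Sequence[float],
    actin_profile: Sequence[float],
    band_slice: slice,
    background_slice: slice,
) -> BlotBand:
    """Background-subtracted optical-density ratio of a target band to actin.

    Both profiles are 1-D densitometric scans of the same lane.  Band OD is
    the profile sum over ``band_slice`` minus the median of the
    ``background_slice`` strip times the band width; the same rule is
    applied to the actin profile, so a shared flat background cancels in
    the ratio.
    """

    def _od(profile: Sequence[float]) -> float:
        prof = np.asarray(profile, dtype=float)
        if prof.ndim != 1 or prof.size == 0:
            raise ValueError("profile must be a non-empty 1-D array")
        band = prof[band_slice]
        bg = prof[background_slice]
        if band.size == 0 or bg.size == 0:
            raise ValueError("empty band or background strip")
        return max(float(band.sum() - np.median(bg) * band.size), 0.0)

    return BlotBand(lane_id=lane_id, target_od=_od(target_profile), actin_od=_od(actin_profile))


def synthetic_layered_image(
    layer_means: Mapping[str, float],
    layer_height_px: int = 20,
    width_px: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple:
    """Synthetic retina section: one horizontal band per layer, Poisson noise.

    Returns ``(image, polygons)`` where ``polygons[layer]`` is the rectangle
    enclosing exactly that band's pixel centers.  Ground truth for each
    layer sum is ``layer_means[layer] * layer_height_px * width_px`` in
    expectation (exact when the rng is None, which disables noise).
    """
    missing = [l for l in LAYERS if l not in layer_means]
    if missing:
        raise ValueError(f"missing layer means: {missing}")
    h = layer_height_px * len(LAYERS)
    image = np.zeros((h, width_px))
    polygons = {}
    for i, layer in enumerate(LAYERS):
        y0, y1 = i * layer_height_px, (i + 1) * layer_height_px
        image[y0:y1, :] = layer_means[layer]
        polygons[layer] = [
            (-0.5, y0 - 0.5), (width_px - 0.5, y0 - 0.5),
            (width_px - 0.5, y1 - 0.5), (-0.5, y1 - 0.5),
        ]
    if rng is not None:
        image = np.random.default_rng(rng).poisson(image).astype(float)
    return image, polygons
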