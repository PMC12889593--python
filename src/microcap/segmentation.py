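"""Four-domain segmentation of 3-channel microcap z-stacks.

Each voxel is assigned to one of four spatial domains from the three
fluorescence channels:

* microspheres from the AF594 channel by Otsu thresholding;
* hydrogel from the Calcofluor White channel by Otsu thresholding, followed
  by per-slice region filling (the stain only decorates an outer ~10 μm
  shell, so the cap core is unstained and must be filled in) and discarding
  of very small regions;
* the coupon by an edge detector along z on the FITC channel (the coupon
  surface reflects into that channel), deliberately biased toward labeling
  voxels as coupon rather than water or hydrogel;
* every remaining voxel is water.

Precedence when masks overlap is coupon > microsphere > hydrogel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import CouponNotFoundError, DegenerateHistogramError, NoHydrogelError
from .volumes import (
    LABEL_COUPON,
    LABEL_HYDROGEL,
    LABEL_MICROSPHERE,
    LABEL_WATER,
    ChannelStack,
    DomainLabelVolume,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    histogram_bins:
        Bin count for Otsu thresholding; intensities are min-max scaled
        before binning so the result is invariant to affine intensity
        rescaling and to the input bit depth.
    min_region_voxels:
        Connected components of the filled hydrogel mask smaller than this
        are discarded ("very small regions"); 26-connectivity in 3-D.
    coupon_gradient_window:
        Number of bottom z-layers searched for the coupon edge; ``None``
        means the lower half of the stack.
    coupon_bias_layers:
        Extra layers *above* the detected edge also labeled coupon, biasing
        ambiguous voxels toward the coupon rather than water or hydrogel.
    coupon_min_drop_fraction:
        A column's edge counts as detected only if its strongest
        positive-to-negative transition reaches this fraction of the
        strongest transition anywhere; weaker columns fall back to the modal
        detected plane.
    max_sphere_fraction:
        Plausibility gate for the microsphere mask.  The spheres are a
        sparse minority phase (0.01 wt% loading, well under 1% of the
        volume); if the AF594 threshold classifies more than this fraction
        of voxels as sphere, the histogram had no genuine sphere class (the
        threshold split the background noise) and an empty mask is returned
        with a warning.
    """

    histogram_bins: int = 256
    min_region_voxels: int = 64
    coupon_gradient_window: int | None = None
    coupon_bias_layers: int = 1
    coupon_min_drop_fraction: float = 0.25
    max_sphere_fraction: float = 0.10

    def __post_init__(self):
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.min_region_voxels < 0:
            raise ValueError("min_region_voxels must be >= 0")
        if self.coupon_bias_layers < 0:
            raise ValueError("coupon_bias_layers must be >= 0")


DEFAULT_PARAMS = SegmentationParams()


def otsu_threshold(intensities: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The input is min-max scaled onto [0, 1] and binned into ``bins`` equal
    bins; candidate thresholds are the interior bin edges, class membership
    is "at or below the edge" versus "above", and class means use bin
    centers.  Ties are broken toward the lowest qualifying edge.  The
    returned threshold is mapped back to the original intensity scale;
    foreground is ``intensities > threshold``.

    Raises
    ------
    DegenerateHistogramError
        If the input holds fewer than two distinct values.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DegenerateHistogramError("empty input")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant input has no threshold")

    counts, _ = np.histogram((x - lo) / (hi - lo), bins=bins, range=(0.0, 1.0))
    centers = (np.arange(bins) + 0.5) / bins
    w = counts / counts.sum()
    # cumulative weight and mean below each interior edge k (bins 0..k-1)
    cum_w = np.cumsum(w)[:-1]
    cum_m = np.cumsum(w * centers)[:-1]
    total_m = float(np.sum(w * centers))
    w0, w1 = cum_w, 1.0 - cum_w
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_m / w0
        mu1 = (total_m - cum_m) / w1
        sigma_b2 = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b2))  # argmax returns the first (lowest) maximizer
    edge = (k + 1) / bins
    return lo + edge * (hi - lo)


def segment_microspheres(stack: ChannelStack, params: SegmentationParams = DEFAULT_PARAMS) -> np.ndarray:
    """Binary microsphere mask from the AF594 channel.

    A stack may legitimately contain no spheres; a degenerate (constant)
    channel yields an empty mask with a logged warning instead of an error.
    """
    try:
        thr = otsu_threshold(stack.af594, params.histogram_bins)
    except DegenerateHistogramError:
        logger.warning("AF594 channel is degenerate; returning empty microsphere mask")
        return np.zeros(stack.shape, dtype=bool)
    mask = stack.af594 > thr
    frac = mask.mean()
    if frac > params.max_sphere_fraction:
        logger.warning(
            "AF594 threshold labels %.1f%% of voxels as sphere (limit %.1f%%); "
            "no genuine sphere class detected, returning empty mask",
            100 * frac, 100 * params.max_sphere_fraction,
        )
        return np.zeros(stack.shape, dtype=bool)
    return mask


def segment_hydrogel(stack: ChannelStack, params: SegmentationParams = DEFAULT_PARAMS) -> np.ndarray:
    """Binary hydrogel mask from the Calcofluor White channel.

    Otsu threshold -> per-z-slice 2-D hole filling (4-connectivity), capturing
    the unstained cap interior enclosed by the stained shell -> discard
    connected components below ``min_region_voxels`` (26-connectivity).
    """
    try:
        thr = otsu_threshold(stack.cw, params.histogram_bins)
    except DegenerateHistogramError as exc:
        raise NoHydrogelError("CW channel carries no hydrogel signal") from exc
    shell = stack.cw > thr
    filled = np.empty_like(shell)
    for iz in range(shell.shape[0]):
        filled[iz] = ndimage.binary_fill_holes(shell[iz])
    mask = shell | filled
    if params.min_region_voxels > 1:
        mask = _drop_small_components(mask, params.min_region_voxels)
    return mask


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove 26-connected components smaller than ``min_voxels``."""
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[lab]


def detect_coupon_planes(
    stack: ChannelStack, params: SegmentationParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Per-(y, x)-column z-index of the coupon surface in the FITC channel.

    For each column the strongest positive-to-negative transition
    (I[k] - I[k+1]) within the search window marks the reflective surface
    layer k.  Columns whose strongest drop is weak (below
    ``coupon_min_drop_fraction`` of the global strongest) take the modal
    detected plane.
    """
    fitc = stack.fitc
    nz = fitc.shape[0]
    window = params.coupon_gradient_window or max(2, nz // 2)
    window = min(window, nz)
    sub = fitc[:window]
    drops = sub[:-1] - sub[1:]  # drop from layer k to k+1
    max_drop = drops.max(axis=0)
    arg = drops.argmax(axis=0)
    global_max = float(max_drop.max(initial=-np.inf))
    if not np.isfinite(global_max) or global_max <= 0:
        raise CouponNotFoundError("no positive-to-negative transition in any column")
    detected = max_drop >= params.coupon_min_drop_fraction * global_max
    if not detected.any():
        raise CouponNotFoundError("no column passes the edge-strength gate")
    modal = int(np.bincount(arg[detected].ravel()).argmax())
    planes = np.where(detected, arg, modal)
    return planes.astype(np.int64)


def segment_coupon(stack: ChannelStack, params: SegmentationParams = DEFAULT_PARAMS) -> np.ndarray:
    """Binary coupon mask: the detected surface layer, everything below it,
    and ``coupon_bias_layers`` above it in each column."""
    planes = detect_coupon_planes(stack, params)
    nz = stack.shape[0]
    zidx = np.arange(nz)[:, None, None]
    return zidx <= (planes[None, :, :] + params.coupon_bias_layers)


def assign_domains(
    sphere_mask: np.ndarray,
    hydrogel_mask: np.ndarray,
    coupon_mask: np.ndarray,
    voxel_size_xyz: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DomainLabelVolume:
    """Combine the three masks into a single-label volume.

    Precedence coupon > microsphere > hydrogel; unclaimed voxels are water.
    """
    if not (sphere_mask.shape == hydrogel_mask.shape == coupon_mask.shape):
        raise ValueError("masks must share one shape")
    labels = np.full(sphere_mask.shape, LABEL_WATER, dtype=np.uint8)
    labels[hydrogel_mask] = LABEL_HYDROGEL
    labels[sphere_mask] = LABEL_MICROSPHERE
    labels[coupon_mask] = LABEL_COUPON
    return DomainLabelVolume(labels, voxel_size_xyz)


def segment_stack(stack: ChannelStack, params: SegmentationParams = DEFAULT_PARAMS) -> DomainLabelVolume:
    """Full segmentation of one stack into the four domains."""
    spheres = segment_microspheres(stack, params)
    hydrogel = segment_hydrogel(stack, params)
    coupon = segment_coupon(stack, params)
    return assign_domains(spheres, hydrogel, coupon, stack.voxel_size_xyz)
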