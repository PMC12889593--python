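"""Per-domain FITC statistics, the microcap partition coefficient, and the
equilibrium plateau check.

The partition coefficient is

    K_P = [FITC]_microcap / [FITC]_water,

where [FITC]_microcap is the voxel-weighted mean FITC intensity over the
union of the hydrogel and microsphere domains and [FITC]_water the mean over
the water domain.  Normalizing by the local water signal removes run-to-run
variation in tracer concentration and detector gain, so K_P values are
comparable across microcaps and coupons.

The water mean deliberately excludes the coupon-adjacent voxel layer and a
one-voxel guard band above it: the coupon surface reflects into the FITC
channel and would otherwise bias the water reference upward.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainEmptyError, InsufficientTraceError, UndefinedPartitionError
from .volumes import DOMAIN_NAMES, LABEL_COUPON, DomainLabelVolume


@dataclass(frozen=True)
class PartitionResult:
    """Domain means and the derived partition coefficient for one microcap."""

    mean_fitc_by_domain: dict[str, float]
    voxel_counts: dict[str, int]
    fitc_microcap: float
    fitc_water: float
    kp: float
    saturated_fraction: float = 0.0


@dataclass(frozen=True)
class IntensityTrace:
    """Mean-intensity time series from single-plane time-lapse imaging."""

    times: np.ndarray  # seconds
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def _check_shapes(fitc_volume: np.ndarray, labels: DomainLabelVolume) -> None:
    if fitc_volume.shape != labels.shape:
        raise ValueError("FITC volume and label volume must share one shape")


def domain_means(fitc_volume: np.ndarray, labels: DomainLabelVolume) -> dict[str, float]:
    """Arithmetic mean FITC intensity per domain; empty domains are absent."""
    _check_shapes(fitc_volume, labels)
    out: dict[str, float] = {}
    for code, name in DOMAIN_NAMES.items():
        m = labels.labels == code
        if m.any():
            out[name] = float(fitc_volume[m].mean())
    return out


def water_mask_excluding_reflection(
    labels: DomainLabelVolume, guard_layers: int = 1
) -> np.ndarray:
    """Water mask with the coupon-adjacent z-layers removed.

    Layers up to ``guard_layers`` above the topmost coupon-labeled layer are
    excluded so the reflective interface cannot leak into the water mean.
    """
    water = labels.mask("water")
    coupon_z = np.nonzero((labels.labels == LABEL_COUPON).any(axis=(1, 2)))[0]
    if coupon_z.size:
        cutoff = int(coupon_z.max()) + guard_layers
        water = water.copy()
        water[: cutoff + 1] = False
    return water


def partition_coefficient(
    fitc_volume: np.ndarray,
    labels: DomainLabelVolume,
    water_guard_layers: int = 1,
    saturation_level: float | None = None,
    water_shell_um: float | None = None,
    baseline_volume: np.ndarray | None = None,
) -> PartitionResult:
    """Compute K_P for one accumulation image.

    The microcap mean is voxel-weighted across the hydrogel-microsphere
    union (not an average of the two domain means).  Saturated voxels are
    only flagged in diagnostics, never clipped or excluded.

    ``water_shell_um`` optionally restricts the water reference to voxels
    within that physical distance of the microcap (the water "immediately
    surrounding" the cap); the default uses the whole water domain.
    ``baseline_volume`` optionally subtracts a characterization-phase FITC
    image (pre-exposure background) from the accumulation image first; off
    by default.

    Raises
    ------
    DomainEmptyError
        If the microcap domain or the (guarded) water domain has no voxels.
    UndefinedPartitionError
        If the water mean is not positive.
    """
    _check_shapes(fitc_volume, labels)
    if baseline_volume is not None:
        if baseline_volume.shape != fitc_volume.shape:
            raise ValueError("baseline volume must match the FITC volume shape")
        fitc_volume = fitc_volume - baseline_volume
    means = domain_means(fitc_volume, labels)
    counts = labels.counts()

    cap_mask = labels.microcap_mask()
    if not cap_mask.any():
        raise DomainEmptyError("microcap domain (hydrogel + microspheres) is empty")
    water = water_mask_excluding_reflection(labels, water_guard_layers)
    if water_shell_um is not None:
        from scipy.ndimage import distance_transform_edt

        dx, dy, dz = labels.voxel_size_xyz
        dist = distance_transform_edt(~cap_mask, sampling=(dz, dy, dx))
        water &= dist <= water_shell_um
    if not water.any():
        raise DomainEmptyError("water domain is empty after the reflection guard")

    fitc_cap = float(fitc_volume[cap_mask].mean())
    fitc_water = float(fitc_volume[water].mean())
    if fitc_water <= 0:
        raise UndefinedPartitionError("water FITC mean is zero; K_P undefined")
    sat = 0.0
    if saturation_level is not None:
        sat = float(np.count_nonzero(fitc_volume >= saturation_level) / fitc_volume.size)
    return PartitionResult(
        mean_fitc_by_domain=means,
        voxel_counts=counts,
        fitc_microcap=fitc_cap,
        fitc_water=fitc_water,
        kp=fitc_cap / fitc_water,
        saturated_fraction=sat,
    )


def equilibrium_reached(
    trace: IntensityTrace,
    tail_fraction: float = 0.25,
    slope_tol: float = 0.01,
) -> tuple[bool, dict[str, float]]:
    """Plateau check on a single-plane time-lapse trace.

    Fits a least-squares line to the last ``tail_fraction`` of the trace and
    normalizes the slope by the tail mean; the system counts as equilibrated
    when the normalized slope magnitude is at most ``slope_tol`` (a fraction
    per minute, e.g. 0.01 = 1%/min).

    Returns the boolean verdict and a diagnostics dict with the tail window
    size, tail mean, and the normalized slope actually measured.
    """
    if not (0 < tail_fraction <= 1):
        raise ValueError("tail_fraction must be in (0, 1]")
    n = trace.times.size
    k = max(int(np.ceil(tail_fraction * n)), 0)
    if k < 5:
        raise InsufficientTraceError(
            f"tail window has {k} samples; at least 5 required"
        )
    t = trace.times[-k:] / 60.0  # minutes
    v = trace.values[-k:]
    slope = float(np.polyfit(t, v, 1)[0])
    mean = float(v.mean())
    if mean == 0:
        norm_slope = np.inf if slope != 0 else 0.0
    else:
        norm_slope = slope / mean
    ok = abs(norm_slope) <= slope_tol
    return bool(ok), {
        "tail_samples": float(k),
        "tail_mean": mean,
        "normalized_slope_per_min": float(norm_slope),
        "slope_tol": float(slope_tol),
    }
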