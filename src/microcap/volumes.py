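"""Shared voxel-volume containers.

A confocal acquisition is represented as a :class:`ChannelStack` holding the
three fluorescence channels of the assay (Calcofluor White for the hydrogel
shell, an AF594-like channel for the embedded microspheres, and FITC for the
diffusing nanodextran plus the coupon surface reflection), all on one voxel
grid with physical voxel sizes in micrometers.  Segmentation produces a
:class:`DomainLabelVolume` assigning every voxel to exactly one of four
spatial domains: the surrounding water, the hydrogel interstitium, the
microsphere interiors, and the solid coupon the cap rests on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer label codes, also used when label volumes are written to TIFF.
LABEL_WATER = 0
LABEL_HYDROGEL = 1
LABEL_MICROSPHERE = 2
LABEL_COUPON = 3

DOMAIN_NAMES = {
    LABEL_WATER: "water",
    LABEL_HYDROGEL: "hydrogel",
    LABEL_MICROSPHERE: "microsphere",
    LABEL_COUPON: "coupon",
}
DOMAIN_CODES = {name: code for code, name in DOMAIN_NAMES.items()}


@dataclass(frozen=True)
class ChannelStack:
    """Three aligned 3-D intensity volumes with axis order (z, y, x).

    Parameters
    ----------
    cw, af594, fitc:
        Non-negative float volumes of identical shape.
    voxel_size_xyz:
        Physical voxel edge lengths ``(dx, dy, dz)`` in micrometers.
    """

    cw: np.ndarray
    af594: np.ndarray
    fitc: np.ndarray
    voxel_size_xyz: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if not (self.cw.shape == self.af594.shape == self.fitc.shape):
            raise ValueError("channel volumes must share one shape")
        if any(v <= 0 for v in self.voxel_size_xyz):
            raise ValueError("voxel sizes must be positive")
        for name in ("cw", "af594", "fitc"):
            arr = getattr(self, name)
            if arr.ndim != 3:
                raise ValueError(f"{name} channel must be 3-D (z, y, x)")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cw.shape

    def channels(self) -> np.ndarray:
        """Channels stacked along a new axis 1, i.e. shape (z, 3, y, x)."""
        return np.stack([self.cw, self.af594, self.fitc], axis=1)


@dataclass(frozen=True)
class DomainLabelVolume:
    """Per-voxel domain assignment with codes {0 water, 1 hydrogel, 2 microsphere, 3 coupon}."""

    labels: np.ndarray
    voxel_size_xyz: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D (z, y, x)")
        bad = set(np.unique(self.labels)) - set(DOMAIN_NAMES)
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, domain: str) -> np.ndarray:
        return self.labels == DOMAIN_CODES[domain]

    def counts(self) -> dict[str, int]:
        """Voxel count per domain; every domain reported, possibly zero."""
        binc = np.bincount(self.labels.ravel(), minlength=len(DOMAIN_NAMES))
        return {DOMAIN_NAMES[code]: int(binc[code]) for code in DOMAIN_NAMES}

    def microcap_mask(self) -> np.ndarray:
        """The total microcap domain: hydrogel union microspheres."""
        return self.mask("hydrogel") | self.mask("microsphere")
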