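"""Synthetic microcap phantoms with exact ground truth.

The phantom emulates the imaging scenario of the accumulation assay: a
hemispherical nanocellulose microcap (diameter kept below 250 μm in default
scenarios) resting on a planar reflective polycarbonate coupon, loaded with
sparse 0.7–0.9 μm fluorescent polystyrene microspheres, bathed in water
carrying a FITC-labelled nanodextran.  At equilibrium the FITC level inside
the cap sits below the bulk-water level (true partition coefficient K_P < 1),
the Calcofluor White stain decorates only an outer shell of the hydrogel
(~10 μm penetration), and the coupon surface reflects into the FITC channel.

Because the geometry is analytic, every voxel's true domain and the true K_P
are known exactly, which makes each downstream stage (segmentation,
quantification, statistics) testable without the original micrographs.

Conventions
-----------
* Physical coordinates are micrometers.  Arrays use axis order (z, y, x);
  voxel (iz, iy, ix) has its center at ((ix+.5)dx, (iy+.5)dy, (iz+.5)dz).
* The coupon occupies every voxel whose center z lies at or below
  ``coupon_z``; the hemisphere is centered on the coupon plane.
* Domain membership is decided by a voxel-center point test (no
  partial-volume weighting).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import GeometryError, OverpackedGeometryError, UndefinedPartitionError
from .volumes import (
    LABEL_COUPON,
    LABEL_HYDROGEL,
    LABEL_MICROSPHERE,
    LABEL_WATER,
    ChannelStack,
    DomainLabelVolume,
)

MAX_DEFAULT_CAP_DIAMETER_UM = 250.0
DEFAULT_SPHERE_RADIUS_RANGE = (0.35, 0.45)  # 0.7-0.9 um diameters


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianNoise:
    """Additive zero-mean Gaussian read noise with standard deviation ``sigma``."""

    sigma: float

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return image + rng.normal(0.0, self.sigma, image.shape)


@dataclass(frozen=True)
class PoissonGaussianNoise:
    """Shot noise plus read noise.

    Photon counts are drawn as Poisson(gain * intensity) and scaled back, so
    the shot-noise standard deviation at intensity I is sqrt(I / gain);
    ``sigma`` is the additive Gaussian read-noise level on the intensity scale.
    """

    gain: float = 1.0
    sigma: float = 0.0

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = rng.poisson(np.maximum(image, 0.0) * self.gain).astype(float) / self.gain
        if self.sigma > 0:
            out = out + rng.normal(0.0, self.sigma, image.shape)
        return out


NoiseModel = GaussianNoise | PoissonGaussianNoise | None


# ---------------------------------------------------------------------------
# scene description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocapGeometry:
    """Analytic description of one microcap scene.

    ``spheres`` is a tuple of ``((x, y, z), radius)`` entries in micrometers;
    every sphere must lie entirely inside the hemispherical cap and strictly
    above the coupon plane.
    """

    cap_center_xy: tuple[float, float]
    cap_radius: float
    coupon_z: float
    spheres: tuple[tuple[tuple[float, float, float], float], ...] = ()
    cw_penetration_depth: float = 10.0

    def __post_init__(self):
        if self.cap_radius <= 0:
            raise GeometryError("cap_radius must be positive")
        if self.cw_penetration_depth <= 0:
            raise GeometryError("cw_penetration_depth must be positive")
        cx, cy = self.cap_center_xy
        for (x, y, z), r in self.spheres:
            if r <= 0:
                raise GeometryError("sphere radius must be positive")
            if z - r <= self.coupon_z:
                raise GeometryError("sphere crosses the coupon plane")
            d = math.dist((x, y, z), (cx, cy, self.coupon_z))
            if d + r > self.cap_radius + 1e-9:
                raise GeometryError("sphere extends outside the hemispherical cap")

    @property
    def cap_center(self) -> tuple[float, float, float]:
        """Hemisphere center, on the coupon plane."""
        return (*self.cap_center_xy, self.coupon_z)


@dataclass(frozen=True)
class ConcentrationField:
    """Equilibrium fluorophore levels per structure, in detector intensity units."""

    fitc_water: float = 100.0
    fitc_hydrogel: float = 70.0
    fitc_microsphere: float = 70.0
    cw_shell: float = 150.0
    af594_sphere: float = 200.0
    coupon_reflection: float = 300.0

    def __post_init__(self):
        for name in ("fitc_water", "fitc_hydrogel", "fitc_microsphere",
                     "cw_shell", "af594_sphere", "coupon_reflection"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, factor: float) -> "ConcentrationField":
        """Uniformly rescale the FITC concentrations (K_P is invariant)."""
        return replace(
            self,
            fitc_water=self.fitc_water * factor,
            fitc_hydrogel=self.fitc_hydrogel * factor,
            fitc_microsphere=self.fitc_microsphere * factor,
        )


@dataclass(frozen=True)
class ImagingConfig:
    """Discretization, blur and noise of the simulated acquisition."""

    voxel_size_xyz: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stack_shape: tuple[int, int, int] = (64, 64, 64)  # (z, y, x)
    noise_model: NoiseModel = None
    blur_sigma_xyz: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_xyz):
            raise GeometryError("voxel sizes must be positive")
        if any(n <= 0 for n in self.stack_shape):
            raise GeometryError("stack shape must be positive")

    def voxel_centers(self):
        """Physical center coordinates along each axis: (zs, ys, xs)."""
        dx, dy, dz = self.voxel_size_xyz
        nz, ny, nx = self.stack_shape
        zs = (np.arange(nz) + 0.5) * dz
        ys = (np.arange(ny) + 0.5) * dy
        xs = (np.arange(nx) + 0.5) * dx
        return zs, ys, xs

    def extent_xyz(self) -> tuple[float, float, float]:
        dx, dy, dz = self.voxel_size_xyz
        nz, ny, nx = self.stack_shape
        return (nx * dx, ny * dy, nz * dz)


# ---------------------------------------------------------------------------
# geometry synthesis
# ---------------------------------------------------------------------------

def make_geometry(
    cap_radius: float,
    coupon_z: float = 2.0,
    n_spheres: int = 0,
    sphere_radius_range: tuple[float, float] = DEFAULT_SPHERE_RADIUS_RANGE,
    cw_penetration_depth: float = 10.0,
    seed: int = 0,
    cap_center_xy: tuple[float, float] | None = None,
    max_attempts_per_sphere: int = 2000,
) -> MicrocapGeometry:
    """Sample a microcap geometry with non-overlapping embedded spheres.

    Spheres are placed by rejection sampling: positions are drawn uniformly
    in the hemisphere shrunk by the sphere radius (so every sphere fits
    entirely inside the cap and above the coupon), and a draw is rejected if
    it intersects a previously placed sphere.  Placement is deterministic for
    a fixed ``seed``.

    Raises
    ------
    OverpackedGeometryError
        If any sphere cannot be placed within ``max_attempts_per_sphere``
        rejection draws, or the requested solid volume fraction exceeds 10%.
    GeometryError
        For non-positive dimensions or spheres larger than the cap.
    """
    if cap_radius <= 0:
        raise GeometryError("cap_radius must be positive")
    if n_spheres < 0:
        raise GeometryError("n_spheres must be non-negative")
    r_lo, r_hi = sphere_radius_range
    if not (0 < r_lo <= r_hi):
        raise GeometryError("sphere_radius_range must be positive and ordered")
    if r_hi >= cap_radius:
        raise GeometryError("sphere radius must be smaller than cap radius")

    cap_volume = (2.0 / 3.0) * math.pi * cap_radius**3
    worst_solid = n_spheres * (4.0 / 3.0) * math.pi * r_hi**3
    if worst_solid > 0.10 * cap_volume:
        raise OverpackedGeometryError(
            f"requested solid volume fraction {worst_solid / cap_volume:.3f} exceeds 0.10"
        )

    if cap_center_xy is None:
        cap_center_xy = (0.0, 0.0)
    rng = np.random.default_rng(seed)
    placed: list[tuple[tuple[float, float, float], float]] = []
    cx, cy = cap_center_xy
    for _ in range(n_spheres):
        r = float(rng.uniform(r_lo, r_hi))
        shrunk = cap_radius - r
        for attempt in range(max_attempts_per_sphere):
            # uniform draw in the upper half-ball of radius `shrunk`
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            v[2] = abs(v[2])
            rad = shrunk * rng.uniform() ** (1.0 / 3.0)
            x, y, z = cx + rad * v[0], cy + rad * v[1], coupon_z + rad * v[2]
            if z - r <= coupon_z:
                continue
            if all(
                math.dist((x, y, z), c) >= r + rc
                for c, rc in placed
            ):
                placed.append(((float(x), float(y), float(z)), r))
                break
        else:
            raise OverpackedGeometryError(
                f"could not place sphere {len(placed) + 1}/{n_spheres} "
                f"after {max_attempts_per_sphere} attempts"
            )
    return MicrocapGeometry(
        cap_center_xy=cap_center_xy,
        cap_radius=cap_radius,
        coupon_z=coupon_z,
        spheres=tuple(placed),
        cw_penetration_depth=cw_penetration_depth,
    )


# ---------------------------------------------------------------------------
# ground truth and rendering
# ---------------------------------------------------------------------------

def _check_fits(geometry: MicrocapGeometry, config: ImagingConfig) -> None:
    ex, ey, ez = config.extent_xyz()
    cx, cy = geometry.cap_center_xy
    r = geometry.cap_radius
    if (cx - r < 0 or cx + r > ex or cy - r < 0 or cy + r > ey
            or geometry.coupon_z + r > ez):
        raise GeometryError("stack does not contain the full cap geometry")


def _label_volume(geometry: MicrocapGeometry, config: ImagingConfig) -> np.ndarray:
    """Voxel-center analytic labeling (water/hydrogel/microsphere/coupon)."""
    zs, ys, xs = config.voxel_centers()
    Z = zs[:, None, None]
    Y = ys[None, :, None]
    X = xs[None, None, :]
    cx, cy = geometry.cap_center_xy
    r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - geometry.coupon_z) ** 2

    labels = np.full(config.stack_shape, LABEL_WATER, dtype=np.uint8)
    in_cap = (r2 <= geometry.cap_radius**2) & (Z > geometry.coupon_z)
    labels[in_cap] = LABEL_HYDROGEL
    for (sx, sy, sz), sr in geometry.spheres:
        # restrict to the sphere's bounding box for speed
        iz = np.searchsorted(zs, [sz - sr, sz + sr])
        iy = np.searchsorted(ys, [sy - sr, sy + sr])
        ix = np.searchsorted(xs, [sx - sr, sx + sr])
        sl = (slice(max(iz[0] - 1, 0), iz[1] + 1),
              slice(max(iy[0] - 1, 0), iy[1] + 1),
              slice(max(ix[0] - 1, 0), ix[1] + 1))
        d2 = ((xs[sl[2]][None, None, :] - sx) ** 2
              + (ys[sl[1]][None, :, None] - sy) ** 2
              + (zs[sl[0]][:, None, None] - sz) ** 2)
        sub = labels[sl]
        sub[d2 <= sr**2] = LABEL_MICROSPHERE
    labels[zs <= geometry.coupon_z] = LABEL_COUPON  # 1-D mask indexes the z axis
    return labels


def ground_truth(
    geometry: MicrocapGeometry,
    config: ImagingConfig,
    field: ConcentrationField,
) -> tuple[DomainLabelVolume, float]:
    """Exact domain labels and the true partition coefficient.

    The true K_P is the volume-weighted mean FITC level over the microcap
    domain (hydrogel plus microsphere voxels) divided by the bulk-water
    level.  With piecewise-constant concentrations that reduces to a
    count-weighted average of the two interior levels.
    """
    _check_fits(geometry, config)
    if field.fitc_water <= 0:
        raise UndefinedPartitionError("fitc_water must be positive for a defined K_P")
    labels = _label_volume(geometry, config)
    n_hyd = int(np.count_nonzero(labels == LABEL_HYDROGEL))
    n_sph = int(np.count_nonzero(labels == LABEL_MICROSPHERE))
    if n_hyd + n_sph == 0:
        raise GeometryError("cap contains no voxels at this resolution")
    mean_cap = (n_hyd * field.fitc_hydrogel + n_sph * field.fitc_microsphere) / (n_hyd + n_sph)
    true_kp = mean_cap / field.fitc_water
    return DomainLabelVolume(labels, config.voxel_size_xyz), float(true_kp)


def reflection_layer_index(geometry: MicrocapGeometry, config: ImagingConfig) -> int | None:
    """z-index of the top coupon voxel layer (where the surface reflects), or None."""
    zs, _, _ = config.voxel_centers()
    below = np.nonzero(zs <= geometry.coupon_z)[0]
    return int(below[-1]) if below.size else None


def render_stack(
    geometry: MicrocapGeometry,
    field: ConcentrationField,
    config: ImagingConfig,
) -> ChannelStack:
    """Render the noisy 3-channel z-stack for a scene.

    Channel construction (before blur and noise, all piecewise-constant):

    * CW: ``cw_shell`` in hydrogel voxels within ``cw_penetration_depth`` of
      the cap's outer spherical surface, zero elsewhere (the stain does not
      reach the cap core).
    * AF594: ``af594_sphere`` inside microspheres, zero elsewhere.
    * FITC: the domain equilibrium concentration everywhere (coupon solid
      carries none), plus ``coupon_reflection`` added in the single voxel
      layer at the coupon surface.

    Gaussian blur (if configured) is applied per channel, then the noise
    model; negative noisy intensities are clipped to zero.  A fixed seed
    reproduces the stack bit-for-bit.
    """
    _check_fits(geometry, config)
    labels = _label_volume(geometry, config)
    zs, ys, xs = config.voxel_centers()
    cx, cy = geometry.cap_center_xy
    r2 = ((xs[None, None, :] - cx) ** 2
          + (ys[None, :, None] - cy) ** 2
          + (zs[:, None, None] - geometry.coupon_z) ** 2)

    cw = np.zeros(config.stack_shape)
    inner = max(geometry.cap_radius - geometry.cw_penetration_depth, 0.0)
    shell = (labels == LABEL_HYDROGEL) & (r2 >= inner**2)
    cw[shell] = field.cw_shell

    af594 = np.zeros(config.stack_shape)
    af594[labels == LABEL_MICROSPHERE] = field.af594_sphere

    fitc = np.zeros(config.stack_shape)
    fitc[labels == LABEL_WATER] = field.fitc_water
    fitc[labels == LABEL_HYDROGEL] = field.fitc_hydrogel
    fitc[labels == LABEL_MICROSPHERE] = field.fitc_microsphere
    k = reflection_layer_index(geometry, config)
    if k is not None:
        fitc[k] += field.coupon_reflection

    chans = [cw, af594, fitc]
    if config.blur_sigma_xyz is not None:
        bx, by, bz = config.blur_sigma_xyz
        dx, dy, dz = config.voxel_size_xyz
        sig = (bz / dz, by / dy, bx / dx)  # voxel units, (z, y, x)
        chans = [gaussian_filter(c, sig) for c in chans]
    if config.noise_model is not None:
        rng = np.random.default_rng(config.seed)
        chans = [config.noise_model.apply(c, rng) for c in chans]
    chans = [np.clip(c, 0.0, None) for c in chans]
    return ChannelStack(*chans, voxel_size_xyz=config.voxel_size_xyz)


def sphere_count_for_weight_percent(
    weight_percent: float,
    cap_radius: float,
    sphere_radius: float = 0.4,
    sphere_density_g_per_cm3: float = 1.05,
    gel_density_g_per_cm3: float = 1.00,
) -> int:
    """Approximate sphere count matching a sphere weight fraction of the cap.

    Converts a loading like 0.01 wt% into a count for a hemispherical cap,
    assuming polystyrene (1.05 g/cm^3) in a dilute gel of roughly water
    density.  This is a documented approximation (densities configurable);
    volumes cancel units so everything stays in micrometers.
    """
    if weight_percent < 0:
        raise ValueError("weight_percent must be non-negative")
    cap_volume = (2.0 / 3.0) * math.pi * cap_radius**3
    sphere_volume = (4.0 / 3.0) * math.pi * sphere_radius**3
    target_mass = (weight_percent / 100.0) * cap_volume * gel_density_g_per_cm3
    return int(round(target_mass / (sphere_volume * sphere_density_g_per_cm3)))
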