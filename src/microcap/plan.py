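"""Experimental design of the accumulation study and end-to-end simulation.

The study crossed four hydrogel types (no microspheres, plain, carboxyl- and
amine-modified microspheres) with up to four FITC-nanodextran tracers.  Only
the sphere-loaded gels saw the full tracer panel; the sphere-free gel was
exposed to the neutral 150 kDa tracer alone and the charged-sphere gels to
the three 150 kDa tracers, giving 11 tested conditions.  With three hydrogel
batches per type, one coupon per (batch, tracer) and three microcap
technical replicates per coupon, the design enumerates to 12 hydrogels,
33 coupons and 99 microcaps.

``simulate_study`` generates a complete synthetic KP dataset over that
design - in fast mode by drawing KP values around per-condition true levels,
or in full mode by rendering a phantom z-stack per microcap and pushing it
through segmentation and quantification.  The default true levels are the
study's own measured equilibrium levels, recovered from the published
log-scale values via K_P = 10^(-pBCF).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import phantom, quantify, segmentation
from .exceptions import MissingConditionError

HYDROGEL_TYPES = ("none", "plain", "carboxyl", "amino")
NANODEXTRANS_ALL = ("Dx-150", "Dx-2000", "DEAE-150", "CM-150")


@dataclass(frozen=True)
class NanodextranSpec:
    """Tracer characterization metadata (instrument values; not used numerically)."""

    name: str
    molecular_weight_kda: float
    charge: str  # neutral | positive | negative
    nta_size_nm: float
    dls_size_nm: float
    zeta_mv: float
    size_range_nm: tuple[float, float]


#: Measured tracer properties (NTA/DLS/ELS), kept as scenario metadata.
NANODEXTRANS = {
    "Dx-150": NanodextranSpec("Dx-150", 150, "neutral", 226, 115, -1.2, (92, 240)),
    "DEAE-150": NanodextranSpec("DEAE-150", 150, "positive", 178, 107, -0.4, (91, 183)),
    "CM-150": NanodextranSpec("CM-150", 150, "negative", 173, 771, -5.7, (173, 1000)),
    "Dx-2000": NanodextranSpec("Dx-2000", 2000, "neutral", 302, 81, -2.4, (81, 330)),
}

#: Published per-condition log-scale accumulation levels (pBCF = -log10 KP).
STUDY_PBCF = {
    ("none", "Dx-150"): 0.153,
    ("plain", "Dx-150"): 0.164,
    ("plain", "Dx-2000"): 0.319,
    ("plain", "DEAE-150"): 0.132,
    ("plain", "CM-150"): 0.160,
    ("carboxyl", "Dx-150"): 0.145,
    ("carboxyl", "DEAE-150"): 0.179,
    ("carboxyl", "CM-150"): 0.135,
    ("amino", "Dx-150"): 0.125,
    ("amino", "DEAE-150"): 0.158,
    ("amino", "CM-150"): 0.068,
}

#: Default true partition coefficients for the synthetic study.
DEFAULT_TRUE_KP = {cond: 10.0 ** (-p) for cond, p in STUDY_PBCF.items()}


@dataclass(frozen=True)
class ExperimentPlan:
    """Condition / batch / coupon / microcap hierarchy of one study."""

    nanodextrans_per_type: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "none": ("Dx-150",),
            "plain": ("Dx-150", "Dx-2000", "DEAE-150", "CM-150"),
            "carboxyl": ("Dx-150", "DEAE-150", "CM-150"),
            "amino": ("Dx-150", "DEAE-150", "CM-150"),
        }
    )
    batches_per_type: int = 3
    microcaps_per_coupon: int = 3

    def conditions(self) -> list[tuple[str, str]]:
        return [(t, nd) for t, nds in self.nanodextrans_per_type.items() for nd in nds]


def default_study_plan() -> ExperimentPlan:
    return ExperimentPlan()


@dataclass(frozen=True)
class PlanCounts:
    hydrogels: int
    coupons: int
    microcaps: int


def enumerate_plan(plan: ExperimentPlan) -> tuple[PlanCounts, pd.DataFrame]:
    """Counts and the flat coupon table implied by a plan.

    hydrogels = types x batches; coupons = sum over types of
    batches x tracers; microcaps = coupons x microcaps_per_coupon.
    """
    rows = []
    coupon_id = 0
    for htype, nds in plan.nanodextrans_per_type.items():
        for batch in range(1, plan.batches_per_type + 1):
            for nd in nds:
                coupon_id += 1
                rows.append({
                    "microsphere_type": htype,
                    "nanodextran": nd,
                    "batch": batch,
                    "coupon": coupon_id,
                })
    table = pd.DataFrame(rows, columns=["microsphere_type", "nanodextran", "batch", "coupon"])
    n_types = len(plan.nanodextrans_per_type)
    counts = PlanCounts(
        hydrogels=n_types * plan.batches_per_type,
        coupons=len(table),
        microcaps=len(table) * plan.microcaps_per_coupon,
    )
    return counts, table


@dataclass(frozen=True)
class KPNoise:
    """Multiplicative KP noise: a batch-level term shared by a coupon's
    microcaps plus an independent per-microcap term, both zero-mean normal."""

    batch_cv: float = 0.05
    microcap_cv: float = 0.05


@dataclass(frozen=True)
class FullModeImaging:
    """Scaled-down phantom used when every microcap is actually rendered.

    The cap is shrunk to fit a small stack (the geometry, shell and sphere
    proportions are preserved) so the full image pipeline stays exercisable
    at interactive cost; absolute sizes are not those of the physical assay.
    """

    stack_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_xyz: tuple[float, float, float] = (0.5, 0.5, 0.5)
    cap_radius: float = 12.0
    coupon_z: float = 2.0
    cw_penetration_depth: float = 4.0
    n_spheres: int = 15
    fitc_water: float = 100.0
    noise: phantom.NoiseModel = phantom.PoissonGaussianNoise(gain=1.0, sigma=5.0)


def _phantom_kp_measurement(
    true_kp: float, cfg: FullModeImaging, seed: int
) -> float:
    """Render one microcap at a target KP and recover KP through the pipeline."""
    geom = phantom.make_geometry(
        cap_radius=cfg.cap_radius,
        coupon_z=cfg.coupon_z,
        n_spheres=cfg.n_spheres,
        cw_penetration_depth=cfg.cw_penetration_depth,
        seed=seed,
        cap_center_xy=(
            cfg.stack_shape[2] * cfg.voxel_size_xyz[0] / 2,
            cfg.stack_shape[1] * cfg.voxel_size_xyz[1] / 2,
        ),
    )
    level = true_kp * cfg.fitc_water
    fld = phantom.ConcentrationField(
        fitc_water=cfg.fitc_water, fitc_hydrogel=level, fitc_microsphere=level
    )
    icfg = phantom.ImagingConfig(
        voxel_size_xyz=cfg.voxel_size_xyz,
        stack_shape=cfg.stack_shape,
        noise_model=cfg.noise,
        seed=seed,
    )
    stack = phantom.render_stack(geom, fld, icfg)
    labels = segmentation.segment_stack(stack)
    return quantify.partition_coefficient(stack.fitc, labels).kp


def simulate_study(
    plan: ExperimentPlan | None = None,
    effect_config: dict[tuple[str, str], float] | None = None,
    noise: KPNoise = KPNoise(),
    seed: int = 0,
    mode: str = "fast",
    imaging: FullModeImaging | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic KP dataset over a plan.

    fast mode draws each microcap's KP as true_kp * (1 + eps_batch + eps_cap);
    full mode renders a phantom stack per microcap (with the same
    multiplicative perturbation applied to the true level first) and runs
    segmentation + quantification.  Bit-reproducible for a fixed seed.
    """
    if mode not in ("fast", "full"):
        raise ValueError("mode must be 'fast' or 'full'")
    plan = default_study_plan() if plan is None else plan
    effect_config = DEFAULT_TRUE_KP if effect_config is None else effect_config
    missing = [c for c in plan.conditions() if c not in effect_config]
    if missing:
        raise MissingConditionError(missing)
    imaging = FullModeImaging() if imaging is None else imaging

    rng = np.random.default_rng(seed)
    _, coupons = enumerate_plan(plan)
    rows = []
    for row in coupons.itertuples(index=False):
        cond = (row.microsphere_type, row.nanodextran)
        true_kp = effect_config[cond]
        eps_b = rng.normal(0.0, noise.batch_cv) if noise.batch_cv > 0 else 0.0
        for mc in range(1, plan.microcaps_per_coupon + 1):
            eps_m = rng.normal(0.0, noise.microcap_cv) if noise.microcap_cv > 0 else 0.0
            kp_target = max(true_kp * (1.0 + eps_b + eps_m), 0.0)
            if mode == "fast":
                kp = kp_target
            else:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                kp = _phantom_kp_measurement(kp_target, imaging, sub_seed)
            rows.append({
                "microsphere_type": row.microsphere_type,
                "nanodextran": row.nanodextran,
                "batch": row.batch,
                "coupon": row.coupon,
                "microcap": mc,
                "kp": kp,
                "true_kp": true_kp,
            })
    return pd.DataFrame(rows)
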