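"""Bioconcentration-factor conversions for cross-study comparison.

Ecotoxicological studies of engineered nanomaterials in periphytic biofilms
report bioconcentration factors (BCF), the mass-per-mass concentration ratio
ug ENM / g biofilm divided by ug ENM / g water, usually only to order of
magnitude; log-scale values (pBCF) are therefore used for comparison.  For
the microcap assay the study-row convention is

    pBCF = -log10(K_P),

the only sign choice under which the printed pair for the neutral 150 kDa
and 2 MDa tracers reproduces the headline 30% partition-coefficient decrease
and the pore-water correction below stays internally consistent.  Literature
values are shipped as a verbatim fixture and never re-derived, which
insulates them from this convention; the merged table carries an explicit
convention column rather than silently mixing scales.

Pore-water correction: a biofilm is not just solids - it contains channels
of pore water in equilibrium with the bulk.  Counting that water in the
denominator mass necessarily lowers the BCF:

    BCF_without = ((m_b_bound + m_pore) / m_b)        / c_bulk
    BCF_with    = ((m_b_bound + m_pore) / (m_b + m_w)) / c_bulk

so BCF_with < BCF_without whenever m_w > 0, and the log-scale shift is
log10((m_b + m_w) / m_b) - exactly log10(2) for biofilm of equal weight to
water.  A dry-weight BCF is converted to wet weight with the conventional
100:1 wet/dry mass ratio (a log shift of exactly 2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_LITERATURE_FIXTURE = "literature_pbcf.csv"

TABLE_COLUMNS = ["type", "biofilm", "size_nm", "hydropathy", "charge",
                 "t_c", "pbcf", "source", "pbcf_convention"]


def kp_to_pbcf(kp: float) -> float:
    """Study-row convention: pBCF = -log10(K_P)."""
    if kp <= 0:
        raise ValueError("kp must be positive")
    return -math.log10(kp)


def pbcf_to_kp(pbcf: float) -> float:
    """Inverse of :func:`kp_to_pbcf`: K_P = 10**(-pBCF)."""
    return 10.0 ** (-pbcf)


def dry_to_wet_bcf(bcf_dry: float, wet_to_dry_ratio: float = 100.0) -> float:
    """Rescale a dry-weight BCF to wet weight (default 100:1 wet/dry mass)."""
    if bcf_dry <= 0:
        raise ValueError("bcf_dry must be positive")
    if wet_to_dry_ratio <= 0:
        raise ValueError("wet_to_dry_ratio must be positive")
    return bcf_dry / wet_to_dry_ratio


@dataclass(frozen=True)
class BCFRecord:
    """A bioconcentration value with basis and provenance."""

    bcf: float
    pbcf: float
    basis: str  # 'wet' | 'dry'
    source: str  # 'this-study' | 'literature-fixture'

    def __post_init__(self):
        if self.bcf <= 0:
            raise ValueError("bcf must be positive")
        if self.basis not in ("wet", "dry"):
            raise ValueError("basis must be 'wet' or 'dry'")

    @classmethod
    def from_kp(cls, kp: float, basis: str = "wet", source: str = "this-study") -> "BCFRecord":
        return cls(bcf=kp, pbcf=kp_to_pbcf(kp), basis=basis, source=source)


@dataclass(frozen=True)
class PoreMassBudget:
    """Mass budget of a porous biofilm at equilibrium with the bulk water.

    m_ndx_b:  tracer mass bound in the biofilm solids
    m_ndx_pore: tracer mass dissolved in the pore water
    m_b:      biofilm solid mass
    m_w:      pore-water mass
    m_ndx_bulk_per_mass: bulk-water tracer concentration (mass per mass)

    If ``m_ndx_pore`` is omitted it is set from the equilibrium condition
    m_ndx_pore = c_bulk * m_w (pore water equilibrated with the bulk).
    """

    m_ndx_b: float
    m_b: float
    m_w: float
    m_ndx_bulk_per_mass: float
    m_ndx_pore: float | None = None

    def __post_init__(self):
        for name in ("m_ndx_b", "m_b", "m_w", "m_ndx_bulk_per_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.m_ndx_pore is None:
            object.__setattr__(self, "m_ndx_pore", self.m_ndx_bulk_per_mass * self.m_w)
        elif self.m_ndx_pore < 0:
            raise ValueError("m_ndx_pore must be non-negative")


@dataclass(frozen=True)
class PoreCorrection:
    bcf_with_pores: float
    bcf_without_pores: float
    delta_pbcf: float


def pore_corrected_bcf(budget: PoreMassBudget) -> PoreCorrection:
    """BCF with and without the pore-water mass in the denominator.

    ``delta_pbcf = log10((m_b + m_w) / m_b)`` is the log-scale gap between
    the two; it depends only on the pore-to-solid mass ratio.
    """
    if budget.m_b <= 0:
        raise ValueError("m_b must be positive")
    if budget.m_ndx_bulk_per_mass <= 0:
        raise ValueError("m_ndx_bulk_per_mass must be positive")
    total = budget.m_ndx_b + budget.m_ndx_pore
    without = (total / budget.m_b) / budget.m_ndx_bulk_per_mass
    with_p = (total / (budget.m_b + budget.m_w)) / budget.m_ndx_bulk_per_mass
    delta = math.log10((budget.m_b + budget.m_w) / budget.m_b)
    return PoreCorrection(with_p, without, delta)


def load_literature_fixture(path=None) -> pd.DataFrame:
    """The packaged survey of published biofilm pBCF values, verbatim."""
    if path is None:
        ref = resources.files("microcap.data") / _LITERATURE_FIXTURE
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    required = {"type", "biofilm", "size_nm", "hydropathy", "charge", "t_c", "pbcf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"literature fixture lacks columns: {sorted(missing)}")
    df = df.copy()
    df["source"] = "literature-fixture"
    df["pbcf_convention"] = "as-published"
    return df[TABLE_COLUMNS]


def build_comparison_table(
    study_records: pd.DataFrame | None = None,
    literature_fixture=None,
) -> pd.DataFrame:
    """Merge study rows (pBCF computed from K_P) with the literature fixture.

    ``study_records`` needs a ``kp`` column plus any of the descriptive
    columns (type, biofilm, size_nm, hydropathy, charge, t_c); missing
    descriptors are left blank.  Literature rows pass through verbatim.
    """
    lit = load_literature_fixture(literature_fixture)
    if study_records is None or len(study_records) == 0:
        return lit.reset_index(drop=True)
    if "kp" not in study_records.columns:
        raise ValueError("study_records must carry a 'kp' column")
    study = study_records.copy()
    study["pbcf"] = study["kp"].astype(float).map(lambda k: f"{kp_to_pbcf(k):.3f}")
    study["source"] = "this-study"
    study["pbcf_convention"] = "-log10(KP)"
    for col in TABLE_COLUMNS:
        if col not in study.columns:
            study[col] = ""
    return pd.concat([study[TABLE_COLUMNS], lit], ignore_index=True)
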