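"""Replicate aggregation and the directional hypothesis battery.

The assay's replicate structure has two levels: three microcaps per coupon
are technical replicates and are averaged, while the three hydrogel batches
(one coupon per batch and tracer) form the statistical sample, so every
condition enters a test with n = 3 batch-level values.

Each biofilm-mimicry effect maps to one-tailed two-sample comparisons run
as Welch's t-tests at alpha = 0.05 (variances are not assumed equal, and
only an effect in the hypothesized direction counts as evidence):

* size exclusion     - the 2 MDa tracer accumulates *less* than the 150 kDa
                       tracer in sphere-loaded caps (1 test);
* volume exclusion   - sphere-loaded caps accumulate *less* than sphere-free
                       caps for the neutral 150 kDa tracer (1 test);
* attachment         - each oppositely charged tracer/sphere pairing
                       accumulates *more* than both of its controls: same
                       tracer with plain spheres, and neutral tracer with
                       the same charged spheres (2 pairings x 2 controls =
                       4 tests).

Normality of each sample is screened with the Shapiro-Wilk test; by default
a failure warns and the battery proceeds.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .exceptions import DegenerateSampleError, DegenerateTestError, MissingConditionError

ALPHA_DEFAULT = 0.05

REQUIRED_COLUMNS = ("microsphere_type", "nanodextran", "batch", "coupon", "microcap", "kp")


def validate_condition_dataset(records: pd.DataFrame, microcaps_per_coupon: int = 3) -> None:
    """Check the replicate bookkeeping of a KP dataset.

    Exactly one coupon per (condition x batch) and ``microcaps_per_coupon``
    microcap replicates per coupon; KP values non-negative.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"dataset lacks columns: {sorted(missing)}")
    if (records["kp"] < 0).any():
        raise ValueError("negative KP values in dataset")
    per_batch = records.groupby(["microsphere_type", "nanodextran", "batch"])["coupon"].nunique()
    if (per_batch != 1).any():
        raise ValueError("each (condition, batch) must use exactly one coupon")
    per_coupon = records.groupby(["microsphere_type", "nanodextran", "batch"])["microcap"].nunique()
    if (per_coupon != microcaps_per_coupon).any():
        raise ValueError(f"each coupon must carry {microcaps_per_coupon} microcap replicates")


def aggregate_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Average the technical (microcap) replicates on each coupon.

    Returns one row per (condition, batch) with the coupon-mean KP; the
    sample size per condition is then the number of batches.  Missing
    replicates are averaged over what is present, with a warning and the
    count recorded in ``n_microcaps``.
    """
    expected = records.groupby(["microsphere_type", "nanodextran", "batch"])["microcap"].nunique()
    if expected.nunique() > 1:
        warnings.warn("unequal microcap replicate counts; averaging available replicates")
    agg = (
        records.groupby(["microsphere_type", "nanodextran", "batch"], as_index=False)
        .agg(kp=("kp", "mean"), n_microcaps=("kp", "size"))
    )
    return agg


@dataclass(frozen=True)
class WelchResult:
    """One-tailed Welch two-sample test result."""

    t_statistic: float
    df: float
    p_one_tailed: float
    direction: str  # 'greater': mean_a > mean_b hypothesized
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_one_tailed <= self.alpha


def welch_one_tailed(
    sample_a, sample_b, direction: str = "greater", alpha: float = ALPHA_DEFAULT
) -> WelchResult:
    """Welch's unequal-variance t-test with a one-sided alternative.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with degrees of
    freedom from the Welch-Satterthwaite approximation; the one-tailed
    p-value is the t-distribution tail probability in the hypothesized
    direction ('greater' or 'less' for mean_a vs mean_b).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise DegenerateTestError("both samples constant and equal; t undefined")
        # zero standard error with distinct means: evidence is one-sided certain
        sign = math.copysign(1.0, a.mean() - b.mean())
        p = 0.0 if (sign > 0) == (direction == "greater") else 1.0
        return WelchResult(math.inf * sign, float(na + nb - 2), p, direction, alpha)
    se2 = va / na + vb / nb
    t_stat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(t_dist.sf(t_stat, df)) if direction == "greater" else float(t_dist.cdf(t_stat, df))
    return WelchResult(float(t_stat), float(df), p, direction, alpha)


# ---------------------------------------------------------------------------
# Shapiro-Wilk
# ---------------------------------------------------------------------------

def _shapiro_coefficients(n: int) -> np.ndarray:
    # Royston's approximation to the order-statistic coefficients
    m = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / math.sqrt(mm)
    u = 1.0 / math.sqrt(n)
    a = np.empty(n)
    an = (((((-2.706056 * u + 4.434685) * u - 2.071190) * u - 0.147981) * u
           + 0.221157) * u + c[-1])
    if n > 5:
        an1 = (((((-3.582633 * u + 5.682633) * u - 1.752461) * u - 0.293762) * u
                + 0.042981) * u + c[-2])
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * an**2 - 2 * an1**2)
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-2], a[1] = an1, -an1
    else:
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * an**2)
        a[1:-1] = m[1:-1] / math.sqrt(phi)
    a[-1], a[0] = an, -an
    return a


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test for 3 <= n <= 50.

    W is built from the order-statistic coefficient construction
    (Royston's small-sample approximation); for n = 3 the closed form
    W = (a1 (x_(3) - x_(1)))^2 / sum((x - xbar)^2) with a1 = 1/sqrt(2)
    applies and the p-value is exact,
    p = (6/pi) (asin(sqrt(W)) - asin(sqrt(3/4))).
    For larger n the p-value uses the published normalizing transformation.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if not (3 <= n <= 50):
        raise ValueError("shapiro_wilk requires 3 <= n <= 50")
    ss = float(np.sum((x - x.mean()) ** 2))
    if ss == 0:
        raise DegenerateSampleError("constant sample; W undefined")
    if n == 3:
        a1 = 1.0 / math.sqrt(2.0)
        w = (a1 * (x[-1] - x[0])) ** 2 / ss
        w = min(w, 1.0)
        if w < 0.75:
            return float(w), 0.0
        p = (6.0 / math.pi) * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        return float(w), float(min(max(p, 0.0), 1.0))
    a = _shapiro_coefficients(n)
    w = float((a @ x) ** 2 / ss)
    w = min(w, 1.0 - 1e-15)
    if n <= 11:
        gamma = -2.273 + 0.459 * n
        g = -math.log(gamma - math.log1p(-w))
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
    else:
        ln_n = math.log(n)
        g = math.log1p(-w)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = math.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
    z = (g - mu) / sigma
    return float(w), float(norm.sf(z))


def confidence_interval_95(sample) -> tuple[float, float]:
    """Two-sided 95% CI on the mean: mean +/- t_{0.975, n-1} s / sqrt(n)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval requires n >= 2")
    half = float(t_dist.ppf(0.975, x.size - 1) * x.std(ddof=1) / math.sqrt(x.size))
    m = float(x.mean())
    return m - half, m + half


# ---------------------------------------------------------------------------
# hypothesis battery
# ---------------------------------------------------------------------------

Condition = tuple[str, str]  # (microsphere_type, nanodextran)


@dataclass(frozen=True)
class HypothesisSpec:
    """One directional comparison: sample A against sample B."""

    effect: str  # size_exclusion | volume_exclusion | attachment
    name: str
    condition_a: Condition
    condition_b: Condition
    direction: str  # expected direction of mean_a relative to mean_b


def default_hypothesis_battery() -> list[HypothesisSpec]:
    """The six primary comparisons of the study design.

    Larger tracer => lower KP; spheres present => lower KP; an oppositely
    charged tracer/sphere pairing => higher KP than each of its two controls.
    """
    return [
        HypothesisSpec("size_exclusion", "Dx-2000 vs Dx-150 (plain spheres)",
                       ("plain", "Dx-2000"), ("plain", "Dx-150"), "less"),
        HypothesisSpec("volume_exclusion", "plain spheres vs no spheres (Dx-150)",
                       ("plain", "Dx-150"), ("none", "Dx-150"), "less"),
        HypothesisSpec("attachment", "CM-150 + amino spheres vs plain spheres",
                       ("amino", "CM-150"), ("plain", "CM-150"), "greater"),
        HypothesisSpec("attachment", "CM-150 + amino spheres vs neutral tracer",
                       ("amino", "CM-150"), ("amino", "Dx-150"), "greater"),
        HypothesisSpec("attachment", "DEAE-150 + carboxyl spheres vs plain spheres",
                       ("carboxyl", "DEAE-150"), ("plain", "DEAE-150"), "greater"),
        HypothesisSpec("attachment", "DEAE-150 + carboxyl spheres vs neutral tracer",
                       ("carboxyl", "DEAE-150"), ("carboxyl", "Dx-150"), "greater"),
    ]


def run_hypothesis_battery(
    records: pd.DataFrame,
    specs: list[HypothesisSpec] | None = None,
    alpha: float = ALPHA_DEFAULT,
    normality: str = "warn",
    aggregated: bool = False,
) -> pd.DataFrame:
    """Run the directional Welch battery on a KP dataset.

    ``records`` is the per-microcap table (technical replicates are averaged
    here first) unless ``aggregated=True``, in which case it is taken to
    already hold one KP per (condition, batch).  ``normality`` is 'warn',
    'strict' (abort on a Shapiro-Wilk failure at alpha) or 'skip'.

    No multiple-testing correction is applied; the returned table carries the
    total number of comparisons so callers can apply their own.
    """
    if normality not in ("warn", "strict", "skip"):
        raise ValueError("normality must be 'warn', 'strict' or 'skip'")
    specs = default_hypothesis_battery() if specs is None else specs
    agg = records if aggregated else aggregate_technical(records)
    samples = {
        (str(ms), str(nd)): grp["kp"].to_numpy(dtype=float)
        for (ms, nd), grp in agg.groupby(["microsphere_type", "nanodextran"])
    }
    needed = {c for s in specs for c in (s.condition_a, s.condition_b)}
    absent = sorted(c for c in needed if c not in samples)
    if absent:
        raise MissingConditionError(absent)

    if normality != "skip":
        for cond in sorted(needed):
            try:
                _, p = shapiro_wilk(samples[cond])
            except DegenerateSampleError:
                if normality == "strict":
                    raise
                warnings.warn(f"condition {cond} is constant; normality screen skipped")
                continue
            if p < alpha:
                msg = f"condition {cond} fails Shapiro-Wilk normality (p={p:.4f})"
                if normality == "strict":
                    raise DegenerateSampleError(msg)
                warnings.warn(msg)

    rows = []
    for spec in specs:
        a = samples[spec.condition_a]
        b = samples[spec.condition_b]
        res = welch_one_tailed(a, b, spec.direction, alpha)
        rows.append({
            "effect": spec.effect,
            "comparison": spec.name,
            "condition_a": "/".join(spec.condition_a),
            "condition_b": "/".join(spec.condition_b),
            "direction": spec.direction,
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "n_a": int(a.size),
            "n_b": int(b.size),
            "t": res.t_statistic,
            "df": res.df,
            "p_one_tailed": res.p_one_tailed,
            "alpha": alpha,
            "significant": res.significant,
            "n_comparisons": len(specs),
        })
    return pd.DataFrame(rows)


def plot_condition_means(agg: pd.DataFrame, path=None, ax=None):
    """Bar chart of per-condition KP means with 95% CI error bars."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stats_rows = []
    for (ms, nd), grp in agg.groupby(["microsphere_type", "nanodextran"]):
        x = grp["kp"].to_numpy(dtype=float)
        lo, hi = confidence_interval_95(x) if x.size >= 2 else (x.mean(), x.mean())
        stats_rows.append((f"{ms}\n{nd}", x.mean(), x.mean() - lo))
    if ax is None:
        _, ax = plt.subplots(figsize=(1.1 * len(stats_rows) + 1.5, 4))
    names, means, errs = zip(*stats_rows)
    ax.bar(range(len(names)), means, yerr=errs, capsize=4, color="#7fa8c9")
    ax.set_xticks(range(len(names)), names, fontsize=8)
    ax.set_ylabel("partition coefficient $K_P$")
    ax.set_title("Condition means with 95% CI (batch replicates)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
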