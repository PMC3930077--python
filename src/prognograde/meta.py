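"""Inverse-variance meta-analysis support statistics.

Everything the factor assessors consume quantitatively lives here: the
log-scale effect representation, fixed- and random-effects pooling with
Cochran's Q and I-squared, confidence-interval overlap and direction
diagnostics, exposure-response gradient detection, and a Woolf odds-ratio
helper for 2x2 tables.

Ratio measures (OR/RR/HR) are analysed on the natural-log scale, where the
line of no effect is 0; standardized mean differences stay on their own
scale. Mixing the two families within one synthesis is an error, never a
silent conversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .model import EffectEstimate

RATIO_MEASURES = frozenset({"OR", "RR", "HR"})


class PrecisionUnavailable(ValueError):
    """Raised when an effect estimate carries no usable confidence interval."""


class InconsistencyNotAssessable(ValueError):
    """Raised when pooling is requested for fewer than two effects."""


def z_quantile(ci_level: float) -> float:
    """Two-sided standard-normal quantile for a confidence level in (0, 1)."""
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0,1), got {ci_level}")
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


@dataclass(frozen=True)
class LogEffect:
    """A study effect on the analysis scale: log for ratios, raw for SMD."""

    theta: float
    se: float
    study_id: str = ""
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se} ({self.study_id})")

    def interval(self) -> tuple[float, float]:
        z = z_quantile(self.ci_level)
        return (self.theta - z * self.se, self.theta + z * self.se)


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity diagnostics.

    ``theta_hat`` is on the analysis scale (log for ratio measures);
    ``i_squared`` is a percentage in [0, 100); ``tau_squared`` is the
    DerSimonian-Laird between-study variance (0 for a fixed-effect pool).
    """

    theta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    p_heterogeneity: float
    i_squared: float
    tau_squared: float
    k: int
    total_n: int = 0
    method: str = "random"

    def __post_init__(self) -> None:
        assert self.df == self.k - 1
        assert self.q >= 0 and self.tau_squared >= 0
        assert 0.0 <= self.i_squared < 100.0


@dataclass(frozen=True)
class OverlapReport:
    min_pairwise_overlap_fraction: float
    any_disjoint: bool


@dataclass(frozen=True)
class DirectionSplit:
    n_risk: int
    n_null_or_unknown: int
    n_protective: int
    straddles_null: bool


@dataclass(frozen=True)
class GradientReport:
    gradient: bool
    direction: str  # "increasing" | "decreasing" | "none"
    applicable: bool = True


def to_log_effect(e: "EffectEstimate", study_id: str = "") -> LogEffect:
    """Convert a reported estimate + CI to the analysis scale.

    For ratio measures theta = ln(point) and the standard error is recovered
    from the CI width on the log scale, se = (ln hi - ln lo) / (2 z); SMDs
    use the identity scale with the analogous width formula.
    """
    if e.ci_low is None or e.ci_high is None:
        raise PrecisionUnavailable(
            f"cannot derive precision: no confidence interval reported"
            f"{' for study ' + study_id if study_id else ''}"
        )
    z = z_quantile(e.ci_level)
    if e.measure in RATIO_MEASURES:
        if min(e.point, e.ci_low, e.ci_high) <= 0:
            raise ValueError(
                f"ratio measure must be positive ({study_id or e.measure})"
            )
        theta = math.log(e.point)
        se = (math.log(e.ci_high) - math.log(e.ci_low)) / (2.0 * z)
    else:
        theta = e.point
        se = (e.ci_high - e.ci_low) / (2.0 * z)
    if se <= 0:
        raise PrecisionUnavailable(
            f"cannot derive precision: degenerate confidence interval"
            f"{' for study ' + study_id if study_id else ''}"
        )
    return LogEffect(theta=theta, se=se, study_id=study_id, ci_level=e.ci_level)


def _pool(effects: Sequence[LogEffect], tau_squared: float) -> tuple[float, float]:
    w = [1.0 / (e.se**2 + tau_squared) for e in effects]
    sw = sum(w)
    theta_hat = sum(wi * e.theta for wi, e in zip(w, effects)) / sw
    return theta_hat, math.sqrt(1.0 / sw)


def _heterogeneity(effects: Sequence[LogEffect]) -> tuple[float, int, float, float]:
    """Cochran's Q (fixed weights), df, chi-square p-value and I^2 (%)."""
    w = [1.0 / e.se**2 for e in effects]
    sw = sum(w)
    mean = sum(wi * e.theta for wi, e in zip(w, effects)) / sw
    q = sum(wi * (e.theta - mean) ** 2 for wi, e in zip(w, effects))
    df = len(effects) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    # guard against floating i2 == 100 at q -> inf
    i2 = min(i2, math.nextafter(100.0, 0.0))
    return q, df, p, i2


def pool_fixed(
    effects: Sequence[LogEffect], ci_level: float = 0.95, total_n: int = 0
) -> PooledResult:
    """Fixed-effect inverse-variance pool with heterogeneity diagnostics."""
    if len(effects) < 2:
        raise InconsistencyNotAssessable(
            "inconsistency not assessable: fewer than two effects"
        )
    q, df, p, i2 = _heterogeneity(effects)
    theta_hat, se_hat = _pool(effects, 0.0)
    z = z_quantile(ci_level)
    return PooledResult(
        theta_hat=theta_hat,
        se_hat=se_hat,
        ci_low=theta_hat - z * se_hat,
        ci_high=theta_hat + z * se_hat,
        q=q,
        df=df,
        p_heterogeneity=p,
        i_squared=i2,
        tau_squared=0.0,
        k=len(effects),
        total_n=total_n,
        method="fixed",
    )


def pool_random(
    effects: Sequence[LogEffect], ci_level: float = 0.95, total_n: int = 0
) -> PooledResult:
    """DerSimonian-Laird random-effects pool.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; study weights then become 1/(se^2 + tau^2). When the
    data are homogeneous (Q <= df) the estimate floors at 0 and the result
    coincides with the fixed-effect pool.
    """
    if len(effects) < 2:
        raise InconsistencyNotAssessable(
            "inconsistency not assessable: fewer than two effects"
        )
    q, df, p, i2 = _heterogeneity(effects)
    w = [1.0 / e.se**2 for e in effects]
    sw = sum(w)
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    theta_hat, se_hat = _pool(effects, tau2)
    z = z_quantile(ci_level)
    return PooledResult(
        theta_hat=theta_hat,
        se_hat=se_hat,
        ci_low=theta_hat - z * se_hat,
        ci_high=theta_hat + z * se_hat,
        q=q,
        df=df,
        p_heterogeneity=p,
        i_squared=i2,
        tau_squared=tau2,
        k=len(effects),
        total_n=total_n,
        method="random",
    )


def interval_overlap_profile(
    intervals: Sequence[tuple[float, float]]
) -> OverlapReport:
    """Pairwise-overlap report over explicit (low, high) intervals.

    The overlap fraction for a pair is the length of the intersection
    divided by the length of the shorter interval; the report carries the
    minimum over all pairs and whether any pair is disjoint (no common
    point at all).
    """
    if len(intervals) < 2:
        raise ValueError("need at least two intervals")
    min_frac = 1.0
    any_disjoint = False
    for (lo1, hi1), (lo2, hi2) in itertools.combinations(intervals, 2):
        inter_lo, inter_hi = max(lo1, lo2), min(hi1, hi2)
        if inter_hi < inter_lo:
            any_disjoint = True
            frac = 0.0
        else:
            shorter = min(hi1 - lo1, hi2 - lo2)
            if shorter <= 0:
                # degenerate (zero-width) interval: inside the other or not
                frac = 1.0
            else:
                frac = (inter_hi - inter_lo) / shorter
        min_frac = min(min_frac, frac)
    return OverlapReport(min_pairwise_overlap_fraction=min_frac, any_disjoint=any_disjoint)


def ci_overlap_profile(effects: Sequence[LogEffect]) -> OverlapReport:
    """Overlap report over the effects' confidence intervals (analysis scale)."""
    if len(effects) < 2:
        raise ValueError("need at least two effects with confidence intervals")
    return interval_overlap_profile([e.interval() for e in effects])


def effect_direction_split(effects: Sequence[LogEffect]) -> DirectionSplit:
    """Classify point estimates by their side of the line of no effect."""
    if not effects:
        raise ValueError("need at least one effect")
    n_risk = sum(1 for e in effects if e.theta > 0)
    n_prot = sum(1 for e in effects if e.theta < 0)
    n_null = len(effects) - n_risk - n_prot
    return DirectionSplit(
        n_risk=n_risk,
        n_null_or_unknown=n_null,
        n_protective=n_prot,
        straddles_null=n_risk > 0 and n_prot > 0,
    )


def detect_gradient(
    levels: Sequence[tuple[float, float]], tolerance: float = 0.0
) -> GradientReport:
    """Detect a strictly monotone exposure-response gradient.

    ``levels`` is an ordered list of (dose, effect point) pairs with strictly
    increasing doses. A gradient is present iff the effect points are
    strictly monotone across all levels, with consecutive differences
    exceeding ``tolerance`` in magnitude. Fewer than three levels cannot
    support the judgment and yield applicable=False.
    """
    doses = [d for d, _ in levels]
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("dose values must be strictly increasing")
    if len(levels) < 3:
        return GradientReport(gradient=False, direction="none", applicable=False)
    pts = [p for _, p in levels]
    diffs = [b - a for a, b in zip(pts, pts[1:])]
    if all(d > tolerance for d in diffs):
        return GradientReport(gradient=True, direction="increasing")
    if all(d < -tolerance for d in diffs):
        return GradientReport(gradient=True, direction="decreasing")
    return GradientReport(gradient=False, direction="none")


def odds_ratio_from_counts(
    a: int, b: int, c: int, d: int, ci_level: float = 0.95
):
    """Woolf odds ratio with 95% CI from a 2x2 table (a,b)/(c,d).

    Applies the +0.5 continuity correction to every cell when any cell is
    zero. A margin (row or column) that is entirely zero leaves the odds
    ratio undefined and raises.
    """
    from .model import EffectEstimate  # local import avoids a cycle

    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("odds ratio undefined: a row or column is entirely zero")
    if any(x == 0 for x in cells):
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = map(float, cells)
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    z = z_quantile(ci_level)
    return EffectEstimate(
        measure="OR",
        point=or_,
        ci_low=or_ * math.exp(-z * se),
        ci_high=or_ * math.exp(z * se),
        ci_level=ci_level,
        adjusted=False,
        n_covariates=0,
    )
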