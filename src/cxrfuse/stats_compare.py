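"""MCC confidence intervals and the CI-based Z-test for comparing models.

Two models evaluated on test sets of size n1, n2 with Matthews
correlation coefficients MCC1, MCC2 and 95% intervals are compared by

    SE_i  = (CI_upper_i - CI_lower_i) / (2 * 1.96)
    dMCC  = MCC2 - MCC1
    dSE   = sqrt(SE1^2 + SE2^2)
    Z     = dMCC / dSE

with a two-sided normal p-value and a 0.05 significance threshold.

The default interval ("wald-proportion") treats the MCC like a binomial
proportion: mcc +/- z * sqrt(mcc * (1 - mcc) / n), clipped to [-1, 1].
An exact Clopper-Pearson mode on the rescaled proportion (mcc + 1) / 2
is available via ``method="clopper-pearson"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "ConfidenceInterval",
    "MetricWithCI",
    "ComparisonResult",
    "mcc_ci",
    "se_from_ci",
    "ci_z_test",
    "format_p",
]

P_RENDER_FLOOR = 1e-5  # p-values below this render as "<0.00001"


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class MetricWithCI:
    """A metric value (MCC) with its confidence interval and test-set size."""

    value: float
    ci: ConfidenceInterval
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.ci.lower - 1e-12 <= self.value <= self.ci.upper + 1e-12:
            raise ValueError("interval does not contain the metric value")

    @property
    def se(self) -> float:
        return se_from_ci(self.ci)


@dataclass(frozen=True)
class ComparisonResult:
    delta_mcc: float
    delta_se: float
    z: float
    p: float
    significant: bool
    alpha: float = 0.05


def _z_for(level: float) -> float:
    # conventional two-sided multiplier; 1.96 at 95% to match Eq-style SE recovery
    if abs(level - 0.95) < 1e-9:
        return 1.96
    return float(stats.norm.ppf(0.5 + level / 2.0))


def mcc_ci(
    mcc: float, n: int, level: float = 0.95, method: str = "wald-proportion"
) -> ConfidenceInterval:
    """Confidence interval for an MCC evaluated on ``n`` samples.

    ``wald-proportion`` (default): mcc +/- z * sqrt(mcc (1 - mcc) / n),
    clipped to [-1, 1]; requires mcc in [0, 1].  ``clopper-pearson``:
    exact beta-quantile interval for the proportion (mcc + 1) / 2 with
    ``n`` trials, mapped back to the MCC scale; valid on all of [-1, 1].
    """
    if not -1.0 <= mcc <= 1.0:
        raise ValueError("mcc must lie in [-1, 1]")
    if n < 1:
        raise ValueError("n must be a positive integer")
    if method == "wald-proportion":
        if mcc < 0:
            raise ValueError(
                "the proportion-style interval needs mcc >= 0; "
                "use method='clopper-pearson' for negative MCCs"
            )
        half = _z_for(level) * math.sqrt(mcc * (1.0 - mcc) / n)
        return ConfidenceInterval(
            lower=max(-1.0, mcc - half), upper=min(1.0, mcc + half), level=level
        )
    if method == "clopper-pearson":
        p = (mcc + 1.0) / 2.0
        k = p * n  # successes (continuous; quantiles accept real shape params)
        alpha = 1.0 - level
        lo = 0.0 if k <= 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1.0))
        hi = 1.0 if k >= n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1.0, n - k))
        return ConfidenceInterval(lower=2 * lo - 1.0, upper=2 * hi - 1.0, level=level)
    raise ValueError(f"unknown CI method {method!r}")


def se_from_ci(ci: ConfidenceInterval) -> float:
    """Standard error recovered from a 95%-style interval: width / (2 * 1.96)."""
    return ci.width / (2.0 * _z_for(ci.level))


def ci_z_test(a: MetricWithCI, b: MetricWithCI, alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Z-test of MCC difference from the two intervals.

    The difference is ``b.value - a.value``; its standard error combines
    the per-model SEs in quadrature.  ``significant`` is ``p < alpha``.
    """
    if abs(a.ci.level - b.ci.level) > 1e-12:
        raise ValueError("intervals must share a confidence level")
    delta_mcc = b.value - a.value
    delta_se = math.hypot(a.se, b.se)
    if delta_se == 0.0:
        if delta_mcc != 0.0:
            raise ValueError("zero combined SE with nonzero MCC difference: Z undefined")
        return ComparisonResult(0.0, 0.0, 0.0, 1.0, False, alpha)
    z = delta_mcc / delta_se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ComparisonResult(delta_mcc, delta_se, z, min(p, 1.0), p < alpha, alpha)


def format_p(p: float, floor: float = P_RENDER_FLOOR) -> str:
    """Render a p-value the way the report tables print it."""
    if p < floor:
        return f"<{floor:.5f}".rstrip("0") if floor != 1e-5 else "<0.00001"
    return f"{p:.5f}"
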