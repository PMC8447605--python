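"""Condition-level summaries and two-sample tests.

Figure-style reporting: per-condition median ± SD, and a two-tailed
two-sample t test between conditions (pooled-variance Student by default,
Welch as an option). Significance stars follow configurable thresholds
(default: one star below p = 0.005). No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as an opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ConditionComparison", "summarize", "t_test",
           "benjamini_hochberg", "stars"]


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sample comparison: group summaries plus the t test."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    sd_a: Optional[float]
    sd_b: Optional[float]
    t_stat: float
    p_value: float
    df: float
    variant: str
    degenerate: bool = False


def summarize(values: Sequence[float]) -> tuple[float, Optional[float], int]:
    """Sample median, SD (n-1 denominator; None when n = 1) and n."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in sample")
    median = float(np.median(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return median, sd, int(arr.size)


def t_test(group_a: Sequence[float], group_b: Sequence[float],
           variant: str = "student", label_a: str = "a",
           label_b: str = "b") -> ConditionComparison:
    """Two-tailed two-sample t test.

    ``variant="student"`` pools the variances (equal-variance assumption);
    ``variant="welch"`` uses the Welch–Satterthwaite approximation. Two
    groups with zero pooled variance give t = 0, p = 1 when their means
    coincide, and a degenerate flag (t = ±inf, p = 0) otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")

    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = ma - mb
    degenerate = False

    if variant == "student":
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        sa, sb = va / na, vb / nb
        se = math.sqrt(sa + sb)
        if sa + sb > 0:
            df = (sa + sb) ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)

    if se == 0.0:
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.inf if diff > 0 else -math.inf
            p = 0.0
            degenerate = True
    else:
        t_stat = diff / se
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))

    med_a, sd_a, _ = summarize(a)
    med_b, sd_b, _ = summarize(b)
    return ConditionComparison(
        group_a=label_a, group_b=label_b, n_a=int(na), n_b=int(nb),
        median_a=med_a, median_b=med_b, sd_a=sd_a, sd_b=sd_b,
        t_stat=float(t_stat), p_value=float(p), df=float(df),
        variant=variant, degenerate=degenerate)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (step-up false discovery rate)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * p.size / np.arange(1, p.size + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def stars(p_value: float,
          thresholds: Sequence[float] = (0.005,)) -> str:
    """Significance stars: one per threshold the p value falls below."""
    return "*" * sum(p_value < t for t in sorted(thresholds, reverse=True))
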