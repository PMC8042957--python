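"""Modality-agreement statistics: paired t-tests and Pearson correlation.

The agreement between histomorphometric BIC and CT-measured BIC is
summarised per group by a paired two-sided t-test on the per-specimen
differences and by Pearson's correlation coefficient, whose significance
comes from the exact t transform

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2.

Both tests can be computed from raw pairs or directly from printed summary
statistics (mean difference, SD of differences, n; or r and n), so published
tables can be reproduced without the raw specimen data.  P-values are kept
at full precision and also rounded half-away-from-zero to two decimals, the
convention of the tables being reproduced.  Correlation strength labels use
|r| cut-offs 0.40 (weak/moderate) and 0.70 (moderate/strong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (table convention)."""
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


def classify_strength(r: float) -> str:
    """Label correlation strength by |r|: <0.40 weak, <0.70 moderate, else strong."""
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    if a < 0.40:
        return "weak"
    if a < 0.70:
        return "moderate"
    return "strong"


@dataclass
class CorrelationResult:
    n: int
    r: float
    t_stat: float
    p_value: float
    p_value_2dp: float
    strength_label: str
    at_limit: bool = False  # |r| == 1: p is the distribution's limiting value

    def __post_init__(self) -> None:
        if abs(self.r) > 1.0:
            raise ValueError("|r| must be <= 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class PairedComparison:
    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    p_value: float
    p_value_2dp: float
    mean_a: float | None = None
    sd_a: float | None = None
    mean_b: float | None = None
    sd_b: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("paired test needs n >= 2")
        if self.sd_diff < 0:
            raise ValueError("sd_diff must be >= 0")


def pearson_p_from_r(r: float, n: int) -> CorrelationResult:
    """Two-sided P-value of a Pearson coefficient via the Student-t transform."""
    if n < 3:
        raise ValueError("pearson significance needs n >= 3")
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return CorrelationResult(
            n=n, r=r, t_stat=math.inf, p_value=0.0, p_value_2dp=0.0,
            strength_label=classify_strength(r), at_limit=True,
        )
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(
        n=n, r=r, t_stat=t, p_value=p, p_value_2dp=round2(p),
        strength_label=classify_strength(r),
    )


def pearson_from_pairs(x, y) -> CorrelationResult:
    """Sample Pearson coefficient of paired observations, with its P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return pearson_p_from_r(r, n)


def paired_t_from_summary(
    mean_diff: float,
    sd_diff: float,
    n: int,
    mean_a: float | None = None,
    sd_a: float | None = None,
    mean_b: float | None = None,
    sd_b: float | None = None,
) -> PairedComparison:
    """Two-sided paired t-test from the summary of the paired differences."""
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if not (sd_diff > 0):
        raise ValueError("sd_diff must be > 0")
    t = mean_diff / (sd_diff / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedComparison(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff, t_stat=t,
        p_value=p, p_value_2dp=round2(p),
        mean_a=mean_a, sd_a=sd_a, mean_b=mean_b, sd_b=sd_b,
    )


def paired_t_from_pairs(x, y) -> PairedComparison:
    """Two-sided paired t-test on raw pairs (differences x - y, n-1 SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    d = x - y
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    if d.std(ddof=1) == 0:
        if d.mean() != 0:
            raise ValueError("constant non-zero differences: sd_diff = 0")
        # identical pairs: no evidence of any difference
        return PairedComparison(
            n=n, mean_diff=0.0, sd_diff=0.0, t_stat=0.0, p_value=1.0, p_value_2dp=1.0,
            mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)),
            mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)),
        )
    res = paired_t_from_summary(
        float(d.mean()), float(d.std(ddof=1)), n,
        mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)),
        mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)),
    )
    assert abs(res.mean_diff - (res.mean_a - res.mean_b)) < 1e-9
    return res


def build_agreement_table(groups: dict) -> pd.DataFrame:
    """Per-group agreement summary between two paired methods.

    ``groups`` maps a group name to a pair of equal-length sequences
    ``(values_a, values_b)`` — e.g. histology BIC and CT BIC per specimen.
    Each row carries n, mean±SD of both methods and of the differences,
    Pearson r with its P-value, and the paired-t P-value (full precision and
    2-decimal table rounding).
    """
    rows = []
    for name, (a, b) in groups.items():
        paired = paired_t_from_pairs(a, b)
        corr = pearson_from_pairs(a, b)
        rows.append(
            {
                "group": name,
                "n": paired.n,
                "mean_a": paired.mean_a,
                "sd_a": paired.sd_a,
                "mean_b": paired.mean_b,
                "sd_b": paired.sd_b,
                "mean_diff": paired.mean_diff,
                "sd_diff": paired.sd_diff,
                "r": corr.r,
                "r_p": corr.p_value,
                "r_p_2dp": corr.p_value_2dp,
                "strength": corr.strength_label,
                "paired_t_p": paired.p_value,
                "paired_t_p_2dp": paired.p_value_2dp,
            }
        )
    return pd.DataFrame(rows).set_index("group")
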