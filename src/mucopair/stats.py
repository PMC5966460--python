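"""Frequentist machinery: paired t-tests, BH adjustment, detectable effect size.

These are the building blocks of the proteomics differential-expression
pipeline: two-tailed paired t-tests across subjects, Benjamini-Hochberg
step-up q-values over all tested features, and the minimal detectable paired
effect at a given power from the noncentral-t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.power import TTestPower

from .exceptions import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class TestResult:
    """One feature's test outcome."""

    feature: str
    statistic: float
    p_value: float
    effect: float  # mean paired difference (log2 FC or log10 ratio)
    q_value: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def paired_t_test(diffs: np.ndarray, feature: str = "") -> TestResult:
    """Two-tailed one-sample t-test on per-subject paired differences.

    Raises
    ------
    DegenerateDataError
        If fewer than 2 differences are supplied or their sample variance is
        exactly zero (no p-value convention is invented for degenerate input).
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise DegenerateDataError("paired t-test needs >= 2 paired differences")
    if not np.isfinite(d).all():
        raise ValidationError("non-finite paired difference")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError(
            "zero variance among paired differences; t-test undefined")
    n = d.size
    mean = d.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(feature=feature, statistic=float(t),
                      p_value=float(min(p, 1.0)), effect=float(mean))


def paired_t_test_matrix(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray]:
    """Vectorised paired t-test over rows of a (features x subjects) array.

    Returns ``(t, p, effect)`` arrays; rows with zero variance get NaN rather
    than a fabricated p-value.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise DegenerateDataError("need a 2-d array with >= 2 columns")
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    bad = sd == 0.0
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, np.minimum(p, 1.0))
    return t, p, mean


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min_{j : p_(j) >= p_(i)} m * p_(j) / j`` capped at 1, computed as a
    reverse cumulative minimum over the sorted p-values.  Order-preserving:
    the i-th output corresponds to the i-th input.  NaN p-values propagate as
    NaN and do not count toward ``m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    mask = ~np.isnan(p)
    if mask.any() and (p[mask].min() < 0 or p[mask].max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[mask]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.minimum(qv, 1.0)
        out = np.empty(m)
        out[order] = qv
        q[mask] = out
    return q


def detectable_log2fc(n: int, sd_diff: float, alpha: float = 0.05,
                      power: float = 0.80) -> float:
    """Smallest |paired effect| detectable at the given size and power.

    Solves the noncentral-t power equation for a two-tailed paired t-test with
    ``n`` pairs and within-pair difference sd ``sd_diff``; the result scales
    linearly in ``sd_diff``.
    """
    if n < 2:
        raise ValidationError("need n >= 2 pairs")
    if sd_diff <= 0:
        raise ValidationError("sd_diff must be > 0")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if power <= alpha:
        raise ValidationError("requested power must exceed alpha")
    dz = TTestPower().solve_power(nobs=n, alpha=alpha, power=power,
                                  alternative="two-sided")
    return float(dz * sd_diff)


def paired_power(delta: float, n: int, sd_diff: float,
                 alpha: float = 0.05) -> float:
    """Analytic power of the two-tailed paired t-test (noncentral t)."""
    if n < 2 or sd_diff <= 0:
        raise ValidationError("need n >= 2 and sd_diff > 0")
    dz = abs(delta) / sd_diff
    return float(TTestPower().power(effect_size=dz, nobs=n, alpha=alpha,
                                    alternative="two-sided"))
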