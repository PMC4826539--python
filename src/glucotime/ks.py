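"""Kolmogorov-Smirnov tests for daily timing distributions.

The non-adherence null for a ward-day is that measurement times are
Uniform(0, 24): a nurse drawing blood glucose at protocol times (before the
three meals and at bedtime) produces a strongly four-modal day, so a
*significant* one-sample KS p-value (p < 0.05) is evidence of adherence.
The two-sample test compares consecutive days to detect distributional
change without any parametric null.

Minute-resolution times carry ties, which violate the continuity assumption
behind the asymptotic two-sample p-value; a pooled-resampling bootstrap
p-value is available for tie-heavy data and the method used is always
reported in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import StudyPanel

import pandas as pd

ALPHA_DEFAULT = 0.05
EXACT_MAX_N = 150  # exact 1S p-value up to this n, asymptotic above


@dataclass(frozen=True)
class KSResult:
    """Outcome of a 1S or 2S KS test.

    ``method == 'not_computable'`` marks a day (or pair) that could not be
    tested (no data); it is distinct from p = 1 and propagates as missing.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int | None = None
    method: str = "asymptotic"

    @property
    def computable(self) -> bool:
        return self.method != "not_computable"

    def significant(self, alpha: float = ALPHA_DEFAULT) -> bool | None:
        if not self.computable:
            return None
        return self.p_value < alpha


def _not_computable(n1: int = 0, n2: int | None = None) -> KSResult:
    return KSResult(float("nan"), float("nan"), n1, n2, "not_computable")


def ks1_uniform(timings, method: str = "auto", exact_max_n: int = EXACT_MAX_N) -> KSResult:
    """One-sample KS test of a day's timings against Uniform(0, 24).

    The statistic is D = sup_y |F_n(y) − y/24|, the maximal gap between the
    day's empirical CDF and the uniform CDF.  ``method`` is ``'exact'``,
    ``'asymptotic'`` or ``'auto'`` (exact for n ≤ ``exact_max_n``).
    """
    x = np.asarray(timings, dtype=float)
    if x.size == 0:
        return _not_computable()
    if method == "auto":
        method = "exact" if x.size <= exact_max_n else "asymptotic"
    scipy_mode = {"exact": "exact", "asymptotic": "asymp"}[method]
    res = stats.kstest(x, stats.uniform(loc=0.0, scale=24.0).cdf, method=scipy_mode)
    return KSResult(float(res.statistic), float(res.pvalue), int(x.size), None, method)


def ks1_critical_value(n: int, alpha: float = ALPHA_DEFAULT, method: str = "auto",
                       exact_max_n: int = EXACT_MAX_N) -> float:
    """Critical D for the 1S test: p < alpha  ⇔  D > this value.

    Uses the exact finite-n two-sided distribution (scipy.stats.kstwo) or
    the asymptotic Kolmogorov limit; both survival functions are strictly
    decreasing in D, so thresholding D is equivalent to thresholding p.
    """
    if method == "auto":
        method = "exact" if n <= exact_max_n else "asymptotic"
    if method == "exact":
        return float(stats.kstwo.isf(alpha, n))
    return float(stats.kstwobign.isf(alpha) / np.sqrt(n))


def ks2(
    timings_a,
    timings_b,
    method: str = "asymptotic",
    n_boot: int = 1000,
    random_state=None,
) -> KSResult:
    """Two-sample KS test between two days' timings.

    ``method='bootstrap'`` replaces the asymptotic p-value with a pooled
    permutation-bootstrap one (both samples redrawn with replacement from the
    pooled data, ``n_boot`` replicates), which tolerates heavy ties.
    """
    a = np.asarray(timings_a, dtype=float)
    b = np.asarray(timings_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return _not_computable(a.size, b.size)
    res = stats.ks_2samp(a, b, method="asymp")
    d_obs = float(res.statistic)
    if method == "asymptotic":
        return KSResult(d_obs, float(res.pvalue), a.size, b.size, "asymptotic")
    if method != "bootstrap":
        raise ValueError(f"unknown 2S method {method!r}")
    rng = np.random.default_rng(random_state)
    pooled = np.concatenate([a, b])
    exceed = 0
    for _ in range(n_boot):
        ra = rng.choice(pooled, size=a.size, replace=True)
        rb = rng.choice(pooled, size=b.size, replace=True)
        if stats.ks_2samp(ra, rb, method="asymp").statistic >= d_obs:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return KSResult(d_obs, float(p), a.size, b.size, "bootstrap")


# ---------------------------------------------------------------------------
# panel-level drivers (the CLI's `ks` subcommand)

def panel_ks1(panel: StudyPanel, method: str = "auto") -> pd.DataFrame:
    """1S-KS per ward-day: ward, day_index, n, statistic, p_value, neglog10_p."""
    rows = []
    for (w, d), wd in sorted(panel.grid.items()):
        r = ks1_uniform(wd.timings, method=method)
        rows.append(
            dict(ward=w, day_index=d, n=wd.n, statistic=r.statistic,
                 p_value=r.p_value,
                 neglog10_p=-np.log10(r.p_value) if r.computable and r.p_value > 0 else np.nan,
                 method=r.method)
        )
    return pd.DataFrame(rows)


def panel_ks2(panel: StudyPanel, method: str = "asymptotic",
              n_boot: int = 1000, random_state=None) -> pd.DataFrame:
    """2S-KS of each day against its previous day, per ward.

    ``day_index`` labels the *current* day of the (day−1, day) pair.
    """
    rows = []
    for w in panel.wards:
        days = panel.ward_days(w)
        for prev, curr in zip(days[:-1], days[1:]):
            r = ks2(prev.timings, curr.timings, method=method,
                    n_boot=n_boot, random_state=random_state)
            rows.append(
                dict(ward=w, day_index=curr.day_index, n_prev=prev.n, n_curr=curr.n,
                     statistic=r.statistic, p_value=r.p_value, method=r.method)
            )
    return pd.DataFrame(rows)
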