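"""Monte-Carlo power of the daily uniformity test.

A non-significant 1S-KS day may reflect adherence-shaped data at too small a
sample size rather than genuine non-adherence.  To separate the two, each
observed day is treated as its own alternative hypothesis: the day's
empirical CDF is linearly interpolated, ``B`` synthetic days of the same
size are drawn from it by inverse-transform sampling, and the power is the
fraction of synthetic days on which the uniformity test rejects at level
alpha.  Wards whose mean *or* median daily power reaches the threshold
(default 90 %) are classified as adequately powered for adherence
assessment.

Two-day pooling windows (current day merged with the previous day) are
provided to rescue moderately powered wards at the cost of assuming the
care process is stable across consecutive days.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ks import ALPHA_DEFAULT, ks1_critical_value
from .records import StudyPanel, WardDay

B_DEFAULT = 5000
POWER_THRESHOLD_DEFAULT = 0.90


class DegenerateDistributionError(ValueError):
    """Raised when a day has < 2 distinct timings: its interpolated CDF has
    no interior and simulated power is undefined."""


@dataclass(frozen=True)
class EmpiricalCDF:
    """Linearly interpolated empirical CDF of one day's timings.

    Knots are the order statistics (y_(k), k/n); duplicate values collapse
    to a single knot keeping the maximal F (a point mass).  A left anchor
    at (y_(1), 0) closes the first interval, so the simulated support is
    exactly [min, max] of the observed day.
    """

    knots_t: np.ndarray  # ascending hours, first value duplicated as anchor
    knots_F: np.ndarray  # strictly ascending after the 0 anchor; ends at 1

    def __call__(self, t):
        """F(t); 0 below the smallest observation, right-continuous jumps."""
        return np.interp(t, self.knots_t[1:], self.knots_F[1:], left=0.0)

    def inverse(self, u):
        """Inverse-transform a uniform draw u ∈ (0, 1] to an hour.

        Locates the knot interval (t1, t2] with F(t1) < u ≤ F(t2) and
        returns t1 + (t2 − t1)·(u − F(t1))/(F(t2) − F(t1)); u at or below
        the first knot's F returns that knot's t (the anchored minimum).
        Piecewise linearity makes this a single linear interpolation in u.
        """
        return np.interp(u, self.knots_F, self.knots_t)


def fit_ecdf(timings) -> EmpiricalCDF:
    """Build the interpolated empirical CDF of a day's timings."""
    y = np.sort(np.asarray(timings, dtype=float))
    distinct = np.unique(y)
    if distinct.size < 2:
        raise DegenerateDistributionError(
            f"need >= 2 distinct timings, got {distinct.size}"
        )
    n = y.size
    # collapse ties: knot at each distinct value with the max cumulative F
    idx = np.searchsorted(y, distinct, side="right")
    F = idx / n
    knots_t = np.concatenate([[distinct[0]], distinct])
    knots_F = np.concatenate([[0.0], F])
    return EmpiricalCDF(knots_t, knots_F)


def sample_inverse(cdf: EmpiricalCDF, u):
    """Inverse-CDF sample at u ∈ (0, 1] (scalar or array)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr <= 0) | (u_arr > 1)):
        raise ValueError("u must lie in (0, 1]")
    out = cdf.inverse(u_arr)
    return float(out) if np.isscalar(u) else out


def _substream(seed: int, ward_id: str, day_index: int) -> np.random.Generator:
    """Deterministic per-(ward, day) substream of a master seed.

    Children are spawned as SeedSequence([master, crc32(ward), day]) so the
    result is independent of evaluation order and parallelizable.
    """
    ward_key = zlib.crc32(str(ward_id).encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), ward_key, int(day_index)])
    )


def simulate_day_power(
    day: WardDay,
    B: int = B_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    method: str = "auto",
) -> float:
    """Simulated power of the 1S-KS uniformity test for one observed day.

    Each of the B iterations draws ``day.n`` timings by inverse-transform
    sampling from the day's interpolated empirical CDF and tests them
    against Uniform(0, 24); the power is the rejection fraction.  The KS
    statistic of every replicate is compared against the critical value at
    ``alpha`` (equivalent to thresholding the p-value, and vectorizable).
    """
    if B <= 0:
        raise ValueError("B must be a positive number of iterations")
    cdf = fit_ecdf(day.timings)  # raises DegenerateDistributionError
    n = day.n
    if rng is None:
        rng = _substream(seed, day.ward_id, day.day_index)
    crit = ks1_critical_value(n, alpha=alpha, method=method)
    u = rng.random((B, n))
    sims = cdf.inverse(u)
    s = np.sort(sims, axis=1) / 24.0  # uniform CDF values of order stats
    k = np.arange(1, n + 1)
    d_plus = (k / n - s).max(axis=1)
    d_minus = (s - (k - 1) / n).max(axis=1)
    D = np.maximum(d_plus, d_minus)
    return float(np.mean(D > crit))


@dataclass
class PowerProfile:
    """Per-day simulated power for one ward plus the high-power call."""

    ward_id: str
    daily_power: dict[int, float]  # day_index -> power; absent when no data
    n_iterations: int
    seed: int
    threshold: float = POWER_THRESHOLD_DEFAULT
    mean_power: float = field(init=False)
    median_power: float = field(init=False)
    high_power: bool = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array([v for v in self.daily_power.values()], dtype=float)
        if vals.size:
            self.mean_power = float(vals.mean())
            self.median_power = float(np.median(vals))
        else:
            self.mean_power = float("nan")
            self.median_power = float("nan")
        self.high_power = bool(
            vals.size
            and (self.mean_power >= self.threshold or self.median_power >= self.threshold)
        )


def ward_power(
    panel: StudyPanel,
    ward: str,
    B: int = B_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    threshold: float = POWER_THRESHOLD_DEFAULT,
    seed: int = 0,
    days: list[WardDay] | None = None,
) -> PowerProfile:
    """Simulate daily power across a ward and classify it.

    Days with < 2 distinct timings (including empty days) are skipped and
    reported as missing, exactly the days on which the test itself is
    missing.  ``days`` overrides the panel's ward-days (used for pooled
    two-day windows).
    """
    if days is None:
        days = panel.ward_days(ward)
    daily: dict[int, float] = {}
    for wd in days:
        try:
            daily[wd.day_index] = simulate_day_power(wd, B=B, alpha=alpha, seed=seed)
        except DegenerateDistributionError:
            continue
    return PowerProfile(ward, daily, B, seed, threshold)


def two_day_windows(panel: StudyPanel, ward: str) -> list[WardDay]:
    """Pool each day with its previous day into n_days − 1 windows.

    Window i (labelled by the current day's index, i = 2..n_days) holds the
    union of the two days' timings; its power is interpreted under the
    assumption that the care process did not change between the two days.
    """
    if panel.n_days < 2:
        raise ValueError("need at least 2 days to form windows")
    days = panel.ward_days(ward)
    return [
        WardDay(ward, curr.day_index, np.concatenate([prev.timings, curr.timings]))
        for prev, curr in zip(days[:-1], days[1:])
    ]


def panel_power(
    panel: StudyPanel,
    B: int = B_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    threshold: float = POWER_THRESHOLD_DEFAULT,
    seed: int = 0,
    window: int = 1,
) -> pd.DataFrame:
    """Power profiles for every ward as a tidy table (CLI `power`).

    ``window=2`` evaluates pooled two-day windows instead of single days.
    """
    rows = []
    for w in panel.wards:
        days = two_day_windows(panel, w) if window == 2 else None
        prof = ward_power(panel, w, B=B, alpha=alpha, threshold=threshold,
                          seed=seed, days=days)
        rows.append(
            dict(ward=w, mean_power=prof.mean_power, median_power=prof.median_power,
                 high_power=prof.high_power, n_days_evaluated=len(prof.daily_power),
                 n_iterations=B, window=window)
        )
    return pd.DataFrame(rows)
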