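"""Empirical-CDF inversion and the Monte-Carlo power engine."""

import numpy as np
import pytest

import glucotime as gt
from glucotime.power import (
    DegenerateDistributionError,
    EmpiricalCDF,
    PowerProfile,
    fit_ecdf,
    sample_inverse,
    simulate_day_power,
    two_day_windows,
    ward_power,
)
from glucotime.records import WardDay


def test_ecdf_two_point_interpolation():
    cdf = fit_ecdf([8.0, 12.0])
    assert cdf(8.0) == pytest.approx(0.5)
    assert cdf(10.0) == pytest.approx(0.75)
    assert cdf(12.0) == pytest.approx(1.0)
    assert cdf(5.0) == 0.0


def test_ecdf_three_point_interpolation():
    cdf = fit_ecdf([6.0, 12.0, 18.0])
    assert cdf(9.0) == pytest.approx(0.5)
    assert cdf(18.0) == pytest.approx(1.0)


def test_ecdf_ties_collapse_to_max_F():
    cdf = fit_ecdf([8.0, 8.0, 8.0, 12.0])
    assert cdf(8.0) == pytest.approx(0.75)  # point mass of 3/4 at the minimum


def test_ecdf_degenerate_day_rejected():
    with pytest.raises(DegenerateDistributionError):
        fit_ecdf([7.0, 7.0, 7.0])


def test_inverse_formula_interior_point():
    cdf = EmpiricalCDF(np.array([6.0, 6.0, 12.0, 18.0]),
                       np.array([0.0, 1 / 3, 2 / 3, 1.0]))
    # (t2 − t1)·(u − F(t1))/(F(t2) − F(t1)) + t1 with u = 0.5 in (1/3, 2/3]
    assert sample_inverse(cdf, 0.5) == pytest.approx(9.0)
    assert sample_inverse(cdf, 1.0) == pytest.approx(18.0)  # u = 1: last knot
    assert sample_inverse(cdf, 2 / 3) == pytest.approx(12.0)  # u at a knot
    assert sample_inverse(cdf, 0.2) == pytest.approx(6.0)  # below first knot F


@pytest.mark.parametrize("u", [0.0, -0.1, 1.0001])
def test_inverse_domain_enforced(u):
    cdf = fit_ecdf([6.0, 12.0])
    with pytest.raises(ValueError):
        sample_inverse(cdf, u)


def test_inverse_sampling_reproduces_knot_probabilities(rng):
    """P(X <= t_k) from 50,000 inverse-transform draws matches F(t_k) to
    within the Kolmogorov bound of +/-0.01."""
    cdf = EmpiricalCDF(np.array([6.0, 6.0, 12.0, 18.0]),
                       np.array([0.0, 1 / 3, 2 / 3, 1.0]))
    draws = cdf.inverse(rng.uniform(1e-12, 1, 50_000))
    for t, F in [(6.0, 1 / 3), (12.0, 2 / 3), (18.0, 1.0)]:
        assert np.mean(draws <= t) == pytest.approx(F, abs=0.01)


def test_power_deterministic_given_seed():
    day = WardDay("W", 3, np.linspace(5, 22, 40) + 0.01 * np.arange(40))
    p1 = simulate_day_power(day, B=300, seed=7)
    p2 = simulate_day_power(day, B=300, seed=7)
    assert p1 == p2
    assert p1 != simulate_day_power(day, B=300, seed=8)


def test_self_sampled_power_of_near_uniform_day_stays_near_alpha():
    """A day sitting exactly on the uniform quantiles carries no deviation
    of its own, so resampling it rejects at roughly the alpha rate."""
    n = 80
    day = WardDay("W", 1, 24 * (np.arange(1, n + 1) - 0.5) / n)
    power = simulate_day_power(day, B=2000, seed=5)
    assert power <= 0.12


def test_self_sampled_power_inflated_by_observed_deviation(rng):
    """A generic finite uniform day embeds its own sampling deviation in
    the interpolated CDF, so its self-sampled power exceeds alpha — the
    mechanism by which observed structure translates into power."""
    powers = [
        simulate_day_power(WardDay("W", i, rng.uniform(0, 24, 80)), B=500, seed=2)
        for i in range(20)
    ]
    assert np.mean(powers) > 0.05


def test_packed_day_has_full_power():
    day = WardDay("W", 1, np.linspace(7, 8, 80))
    assert simulate_day_power(day, B=500, seed=1) >= 0.99


def test_power_monotone_in_sample_size(rng):
    """For a fixed adherent 4-modal shape, power grows with daily n."""
    def modal_day(n, idx):
        t = np.concatenate(
            [rng.normal(m, 0.3, n // 4) for m in (7.2, 11.4, 17.2, 21.9)]
        ).clip(0.01, 23.99)
        return WardDay("W", idx, t)

    p_small = np.mean([simulate_day_power(modal_day(20, i), B=400, seed=3)
                       for i in range(8)])
    p_large = np.mean([simulate_day_power(modal_day(100, i), B=400, seed=3)
                       for i in range(8)])
    assert p_large >= p_small


def test_invalid_iteration_count():
    day = WardDay("W", 1, np.array([6.0, 12.0, 18.0]))
    with pytest.raises(ValueError):
        simulate_day_power(day, B=0)


def test_high_power_rule_is_mean_or_median():
    prof = PowerProfile("W", {1: 0.8, 2: 0.95, 3: 0.95}, 100, 0)
    assert prof.median_power == pytest.approx(0.95)
    assert prof.high_power  # median clears 0.90 even though mean = 0.90
    prof_all = PowerProfile("W", {1: 1.0, 2: 1.0}, 100, 0)
    assert prof_all.mean_power == prof_all.median_power == 1.0 and prof_all.high_power
    assert not PowerProfile("W", {1: 0.5, 2: 0.6}, 100, 0).high_power


def test_ward_power_skips_degenerate_days(adherent_panel):
    panel, _ = adherent_panel
    # inject a degenerate and an empty day into a copy of the ward's days
    days = panel.ward_days("W01")
    days[0] = WardDay("W01", 1, np.array([]))
    days[1] = WardDay("W01", 2, np.full(5, 9.0))
    prof = ward_power(panel, "W01", B=100, seed=1, days=days)
    assert set(prof.daily_power) == set(range(3, panel.n_days + 1))


def test_ward_power_all_missing_not_high():
    panel = gt.build_panel([], __import__("datetime").date(2013, 11, 1), 3,
                           wards=["A"])
    prof = ward_power(panel, "A", B=100, seed=1)
    assert prof.daily_power == {} and not prof.high_power


def test_two_day_windows_counts(adherent_panel):
    panel, _ = adherent_panel
    wins = two_day_windows(panel, "W01")
    assert len(wins) == panel.n_days - 1  # day 1 has no window
    days = panel.ward_days("W01")
    for prev, curr, win in zip(days[:-1], days[1:], wins):
        assert win.n == prev.n + curr.n
        assert win.day_index == curr.day_index
    # the study-scale accounting: 61 days -> 60 windows; x6 wards = 360
    assert (61 - 1) * 6 == 360
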