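"""Synthetic ward panels with the timing structure the method assumes.

The generator emulates the daily rhythm of an adherent non-critical-care
ward: four tight normal components of measurement times centred shortly
before the 0800/1200/1800 mealtimes and near 2200 bedtime, plus an
optional wide background component standing in for off-schedule monitoring
(fasting or insulin-infusion patients, hypoglycaemia rechecks).  Defaults
are the cross-ward median estimates reported for adherent wards: component
means 7.23, 11.38, 17.18, 21.94 h with SDs 0.28, 0.34, 0.25, 0.26 h and a
background of SD 5.94 h; the published probabilities (0.22, 0.18, 0.22,
0.20, background 0.12) are medians across wards and sum to 0.94, so they
are renormalized onto the simplex here.  Daily sample sizes are drawn
discrete-uniform on [59, 103], the range of median daily counts among
adequately powered wards.

Scenarios: ``adherent`` (the mixture above), ``uniform`` (complete
non-adherence, Uniform(0, 24)), ``mixed`` (first half of the wards
adherent, rest uniform), and an engineered transition panel that switches
a ward between regimes on a known day.

Draws landing outside [0, 24) are resampled rather than clipped, which
avoids boundary spikes at midnight at the cost of slightly truncating the
background component.  Every ward-day uses its own seed substream, so
panels are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import StudyPanel, WardDay

TABLE_MEANS = (7.23, 11.38, 17.18, 21.94)
TABLE_SDS = (0.28, 0.34, 0.25, 0.26)
TABLE_PROBS = (0.22, 0.18, 0.22, 0.20)
BACKGROUND_MEAN = 11.22
BACKGROUND_SD = 5.94
BACKGROUND_PROB = 0.12


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic ward-panel generator.

    ``daily_n`` is the inclusive (low, high) range of the discrete-uniform
    daily measurement count.  ``day_effect_ar1 = (rho, sd)`` optionally
    perturbs the component logits with a per-ward AR(1) series over days to
    exercise the day-varying mixture model; default none (π constant).
    """

    n_wards: int = 11
    n_days: int = 61
    daily_n: tuple[int, int] = (59, 103)
    means: tuple[float, ...] = TABLE_MEANS
    sds: tuple[float, ...] = TABLE_SDS
    probs: tuple[float, ...] = TABLE_PROBS
    background_mean: float = BACKGROUND_MEAN
    background_sd: float = BACKGROUND_SD
    background_prob: float = BACKGROUND_PROB
    scenario: str = "adherent"
    day_effect_ar1: tuple[float, float] | None = None
    seed: int = 0
    base_probs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds) or len(self.means) != len(self.probs):
            raise ValueError("means, sds and probs must have equal length")
        raw = np.asarray(list(self.probs) + [self.background_prob], dtype=float)
        if np.any(raw < 0) or raw.sum() <= 0:
            raise ValueError(f"invalid probability vector {raw}")
        object.__setattr__(self, "base_probs", raw / raw.sum())
        if self.scenario not in ("adherent", "uniform", "mixed", "transition"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (1 <= self.daily_n[0] <= self.daily_n[1]):
            raise ValueError(f"invalid daily_n range {self.daily_n}")

    @property
    def all_means(self) -> np.ndarray:
        return np.asarray(list(self.means) + [self.background_mean])

    @property
    def all_sds(self) -> np.ndarray:
        return np.asarray(list(self.sds) + [self.background_sd])


def _rng_for(spec_seed: int, ward_idx: int, day: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec_seed), int(ward_idx), int(day)])
    )


def _truncated_normal(rng, mean, sd, size):
    """Normal draws resampled into [0, 24)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < 0) | (out >= 24)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 0) | (out >= 24)
    return out


def _day_probs(spec: GeneratorSpec, rng_ward: np.random.Generator) -> np.ndarray:
    """(n_days, K+1) mixture probabilities, optionally AR(1)-perturbed."""
    base = spec.base_probs
    if spec.day_effect_ar1 is None:
        return np.tile(base, (spec.n_days, 1))
    rho, sd = spec.day_effect_ar1
    logits = np.log(base)
    eps = np.zeros((spec.n_days, base.size))
    eps[0] = rng_ward.normal(0, sd, base.size)
    for d in range(1, spec.n_days):
        eps[d] = rho * eps[d - 1] + rng_ward.normal(0, sd * np.sqrt(1 - rho**2), base.size)
    raw = np.exp(logits + eps)
    return raw / raw.sum(axis=1, keepdims=True)


def _draw_day(spec, rng, probs):
    """One ward-day: (timings, component labels). Label K = background,
    −1 = uniform non-adherence draw."""
    n = int(rng.integers(spec.daily_n[0], spec.daily_n[1] + 1))
    comp = rng.choice(probs.size, size=n, p=probs)
    t = np.empty(n)
    for k in np.unique(comp):
        mask = comp == k
        t[mask] = _truncated_normal(rng, spec.all_means[k], spec.all_sds[k],
                                    int(mask.sum()))
    return t, comp


def _draw_uniform_day(spec, rng):
    n = int(rng.integers(spec.daily_n[0], spec.daily_n[1] + 1))
    return rng.uniform(0.0, 24.0, size=n), np.full(n, -1)


def generate_panel(spec: GeneratorSpec) -> tuple[StudyPanel, pd.DataFrame]:
    """Generate a complete ward × day panel plus the ground-truth labels.

    Returns the panel and a truth table (ward, day_index, time_hours,
    component) where component is the 0-based generating component, the
    last index being the wide background and −1 a uniform (non-adherent)
    draw.  Deterministic given ``spec.seed``; each ward-day has its own
    seed substream.
    """
    wards = [f"W{i + 1:02d}" for i in range(spec.n_wards)]
    grid: dict[tuple[str, int], WardDay] = {}
    truth_rows = []
    for w_idx, ward in enumerate(wards):
        uniform_ward = spec.scenario == "uniform" or (
            spec.scenario == "mixed" and w_idx >= spec.n_wards // 2
        )
        rng_ward = _rng_for(spec.seed, w_idx, 0)
        probs = _day_probs(spec, rng_ward)
        for day in range(1, spec.n_days + 1):
            rng = _rng_for(spec.seed, w_idx, day)
            if uniform_ward:
                t, comp = _draw_uniform_day(spec, rng)
            else:
                t, comp = _draw_day(spec, rng, probs[day - 1])
            order = np.argsort(t)
            grid[(ward, day)] = WardDay(ward, day, t)
            for ti, ci in zip(t[order], comp[order]):
                truth_rows.append((ward, day, float(ti), int(ci)))
    panel = StudyPanel(wards, spec.n_days, grid)
    truth = pd.DataFrame(truth_rows,
                         columns=["ward", "day_index", "time_hours", "component"])
    return panel, truth


def make_transition_scenario(
    spec: GeneratorSpec, switch_day: int, to_uniform: bool = True
) -> tuple[StudyPanel, pd.DataFrame]:
    """Panel whose wards switch regime on ``switch_day``.

    Adherent up to switch_day − 1 and uniform from switch_day on when
    ``to_uniform`` (the reverse otherwise).  The truth table gains a
    ``regime`` column; the engineered change happens inside the
    (switch_day − 1, switch_day) window.
    """
    if not (1 < switch_day <= spec.n_days):
        raise ValueError(f"switch_day must lie in (1, {spec.n_days}]")
    wards = [f"W{i + 1:02d}" for i in range(spec.n_wards)]
    grid: dict[tuple[str, int], WardDay] = {}
    truth_rows = []
    for w_idx, ward in enumerate(wards):
        rng_ward = _rng_for(spec.seed, w_idx, 0)
        probs = _day_probs(spec, rng_ward)
        for day in range(1, spec.n_days + 1):
            rng = _rng_for(spec.seed, w_idx, day)
            uniform_now = (day >= switch_day) == to_uniform
            if uniform_now:
                t, comp = _draw_uniform_day(spec, rng)
            else:
                t, comp = _draw_day(spec, rng, probs[day - 1])
            grid[(ward, day)] = WardDay(ward, day, t)
            regime = "uniform" if uniform_now else "adherent"
            for ti, ci in zip(np.sort(t), comp[np.argsort(t)]):
                truth_rows.append((ward, day, float(ti), int(ci), regime))
    panel = StudyPanel(wards, spec.n_days, grid)
    truth = pd.DataFrame(
        truth_rows,
        columns=["ward", "day_index", "time_hours", "component", "regime"],
    )
    return panel, truth


def adherent_spec(**overrides) -> GeneratorSpec:
    """The default adherent-ward generator (published median parameters)."""
    return GeneratorSpec(**overrides)


def uniform_spec(**overrides) -> GeneratorSpec:
    """Complete non-adherence: timings Uniform(0, 24)."""
    overrides.setdefault("scenario", "uniform")
    return GeneratorSpec(**overrides)
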