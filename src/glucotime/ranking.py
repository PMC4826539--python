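"""Ward ranking and the p-value meta-regression.

Wards are ranked by the proportion of days whose timings deviate
significantly from the uniform non-adherence null, with ties broken by the
median daily p-value.  To quantify how sample size and deviation magnitude
jointly drive the daily evidence, −log10(p) from the one-sample KS test is
regressed on the z-standardized KS effect size D and daily sample size n,
with their interaction:

    −log10 p  =  β0 + β_D·z(D) + β_n·z(n) + β_Dn·z(D)·z(n) + ε

The marginal effect of one predictor at a fixed value of the other is
β_main + β_Dn × other, and an increase Δ in −log10(p) corresponds to a
100·(1 − 10^−Δ) % reduction in the p-value itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .ks import ALPHA_DEFAULT

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-300  # exact-zero p (possible with bootstrap p) floored here


def rank_wards(ks_results: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Rank wards by daily 1S-KS outcomes.

    ``ks_results`` is the per-ward-day table from :func:`glucotime.ks.panel_ks1`
    (columns ward, p_value; NaN p-values are non-computable days and are
    excluded from both ranking keys).  Returns one row per ward with
    prop_significant, median_p, n_days_evaluated and rank (1 = most
    significant; ordering is prop_significant descending, ties broken by
    median_p ascending).  Wards with zero computable days rank last.
    """
    rows = []
    for ward, g in ks_results.groupby("ward"):
        p = g["p_value"].dropna()
        if len(p) == 0:
            logger.warning("ward %s has no computable days; ranked last", ward)
            rows.append(dict(ward=ward, prop_significant=-np.inf,
                             median_p=np.inf, n_days_evaluated=0))
            continue
        rows.append(
            dict(ward=ward, prop_significant=float((p < alpha).mean()),
                 median_p=float(p.median()), n_days_evaluated=int(len(p)))
        )
    out = pd.DataFrame(rows).sort_values(
        ["prop_significant", "median_p", "ward"], ascending=[False, True, True]
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.loc[out["n_days_evaluated"] == 0, "prop_significant"] = np.nan
    out.loc[out["n_days_evaluated"] == 0, "median_p"] = np.nan
    return out.reset_index(drop=True)


class PValueMetaRegression(BaseEstimator):
    """OLS of −log10(p) on standardized KS effect size and sample size.

    Predictors are z-standardized (sample SD, n−1 denominator) inside
    :meth:`fit`, so coefficients are per-SD effects comparable across the
    two drivers of the daily evidence.

    Parameters
    ----------
    p_floor : p-values below this are floored before taking −log10 to avoid
        infinities from exact-zero bootstrap p-values.

    Attributes
    ----------
    beta_effect_, beta_n_, beta_interaction_, intercept_ : coefficients.
    conf_int_ : (4, 2) array of classical OLS 95 % CIs, rows ordered
        (intercept, effect, n, interaction).
    rsquared_ : coefficient of determination.
    scale_mean_, scale_sd_ : the standardization constants, (D, n).
    results_ : the underlying statsmodels results object.
    """

    def __init__(self, p_floor: float = P_FLOOR_DEFAULT):
        self.p_floor = p_floor

    # -- sklearn plumbing ---------------------------------------------------
    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [D, n]")
        return X

    def fit(self, X, y):
        """Fit on X = (effect size D, sample size n) columns, y = −log10 p.

        Requires at least 10 rows with finite y (a meta-regression on fewer
        ward-days is not meaningful and the design is near-singular).
        """
        X = self._validate(X)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        X, y = X[keep], y[keep]
        if len(y) < 10:
            raise ValueError(f"need >= 10 finite ward-days, got {len(y)}")
        self.scale_mean_ = X.mean(axis=0)
        self.scale_sd_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_sd_ <= 1e-12 * (np.abs(self.scale_mean_) + 1.0)):
            raise ValueError("singular design: a predictor is constant")
        z = (X - self.scale_mean_) / self.scale_sd_
        design = sm.add_constant(
            np.column_stack([z[:, 0], z[:, 1], z[:, 0] * z[:, 1]])
        )
        self.results_ = sm.OLS(y, design).fit()
        params = self.results_.params
        self.intercept_ = float(params[0])
        self.beta_effect_ = float(params[1])
        self.beta_n_ = float(params[2])
        self.beta_interaction_ = float(params[3])
        self.conf_int_ = np.asarray(self.results_.conf_int(alpha=0.05))
        self.rsquared_ = float(self.results_.rsquared)
        self.n_obs_ = int(len(y))
        return self

    def transform_targets(self, p_values) -> np.ndarray:
        """−log10(p) with the configured floor applied (and a warning)."""
        p = np.asarray(p_values, dtype=float)
        if np.any(p <= 0):
            logger.warning("flooring %d nonpositive p-values at %g",
                           int((p <= 0).sum()), self.p_floor)
        return -np.log10(np.clip(p, self.p_floor, None))

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        z = (X - self.scale_mean_) / self.scale_sd_
        return (
            self.intercept_
            + self.beta_effect_ * z[:, 0]
            + self.beta_n_ * z[:, 1]
            + self.beta_interaction_ * z[:, 0] * z[:, 1]
        )

    def marginal_effect(self, vary: str, other_fixed_at: float = 1.0) -> float:
        """Change in −log10(p) per unit of one standardized predictor.

        ``vary`` is ``'effect'`` or ``'n'``; ``other_fixed_at`` is the value
        (in SD units) at which the other predictor is held.
        """
        if vary == "effect":
            return marginal_effect(self.beta_effect_, self.beta_interaction_, other_fixed_at)
        if vary == "n":
            return marginal_effect(self.beta_n_, self.beta_interaction_, other_fixed_at)
        raise ValueError("vary must be 'effect' or 'n'")

    @classmethod
    def from_coefficients(cls, beta_effect: float, beta_n: float,
                          beta_interaction: float, intercept: float = 0.0):
        """Assemble a fitted-form model from externally reported coefficients
        (e.g. a published regression table) for marginal-effect arithmetic."""
        m = cls()
        m.beta_effect_ = float(beta_effect)
        m.beta_n_ = float(beta_n)
        m.beta_interaction_ = float(beta_interaction)
        m.intercept_ = float(intercept)
        m.scale_mean_ = np.zeros(2)
        m.scale_sd_ = np.ones(2)
        return m


def fit_meta_regression(
    ks_results: pd.DataFrame, p_floor: float = P_FLOOR_DEFAULT
) -> PValueMetaRegression:
    """Fit the meta-regression from a per-ward-day 1S-KS table.

    Expects columns ``statistic`` (D), ``n`` and ``p_value``; non-computable
    days (NaN) are dropped.
    """
    df = ks_results.dropna(subset=["statistic", "p_value"])
    df = df[df["n"] > 0]
    model = PValueMetaRegression(p_floor=p_floor)
    y = model.transform_targets(df["p_value"].to_numpy())
    return model.fit(df[["statistic", "n"]].to_numpy(dtype=float), y)


def marginal_effect(beta_main: float, beta_interaction: float,
                    other_fixed_at: float = 1.0) -> float:
    """Marginal effect of a predictor in an interaction model:
    β_main + β_interaction × (value of the other predictor)."""
    return float(beta_main + beta_interaction * other_fixed_at)


def p_reduction(delta_neglog10: float, decimals: int | None = 1) -> float:
    """Percent reduction in the p-value from an increase Δ of −log10(p).

    100·(1 − 10^−Δ); rounded to one decimal for reporting by default
    (``decimals=None`` returns the raw value).
    """
    if delta_neglog10 < 0:
        raise ValueError("delta must be >= 0")
    pct = 100.0 * (1.0 - 10.0 ** (-delta_neglog10))
    return pct if decimals is None else float(round(pct, decimals))
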