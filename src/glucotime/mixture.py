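"""Day-indexed concomitant-variable normal mixture for daily timings.

A ward's two months of measurement times are modelled as a K-component
normal mixture whose component means and variances are constant across
days, while the mixing probabilities vary by day through a multinomial
logit on day indicators (a *concomitant variable* model):

    h(y_ij | w_ij, α, μ, σ²) = Σ_k π_k(w_ij, α) · N(y_ij; μ_k, σ_k²)
    π_k(w_ij, α) = exp(w_ij'α_k) / Σ_u exp(w_ij'α_u),   α_1 ≡ 0

where y_ij is the j-th timing on day i and w_ij holds the indicator
variables of days 2..D.  Because the concomitant design is a saturated set
of day indicators, the logit M-step has a closed form: π_k on day d is the
mean responsibility of component k among that day's observations; α is
recovered as the day-wise log-odds against component 1.

The number of components is selected by the integrated classification
likelihood, ICL = −2·logL + ν·log(n) + 2·entropy, a BIC penalized further
by the classification entropy of the responsibilities; lower is better.
An adherent ward is expected to yield exactly four *narrow* components
(SD < 1 h) centred before the three mealtimes and near bedtime, plus wide
background components absorbing off-schedule measurements (fasting or
insulin-infusion monitoring, hypoglycaemia rechecks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

SD_THRESHOLD_DEFAULT = 1.0  # hours; narrow-component cut
MEAL_TIMES_DEFAULT = (8.0, 12.0, 18.0, 22.0)
SLOT_NAMES = ("breakfast", "lunch", "dinner", "bedtime")
VAR_FLOOR_DEFAULT = 1e-4  # h²; guards against spikes on tied minute data


class _ComponentCollapse(RuntimeError):
    pass


class ConcomitantNormalMixture(BaseEstimator):
    """EM fit of the day-indexed concomitant normal mixture.

    Parameters
    ----------
    n_components : K, number of normal components.
    n_starts : EM restarts; the first is a quantile-based start (component
        means at the ((k − 0.5)/K)-quantiles of the data), the rest draw
        random responsibilities. Best final log-likelihood wins.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap per start.
    var_floor : lower bound on component variances (h²).
    random_state : seed for the random starts.

    Attributes
    ----------
    means_, sds_ : (K,) component means / SDs in hours, sorted by mean.
    days_ : sorted unique day indices seen in the data (days with zero
        observations have no indicator column and no defined π).
    day_probs_ : (D, K) day-wise mixing probabilities, rows sum to 1.
    alpha_ : (K − 1, D) multinomial-logit coefficients against component 1
        in the (intercept, day-2..day-D indicator) parametrization.
    loglik_, bic_, icl_, entropy_ : fit and selection statistics.
    n_parameters_ : ν = 2K + (K − 1)·D free parameters.
    responsibilities_ : (n_obs, K) posterior component probabilities.
    converged_, n_iter_ : convergence diagnostics of the winning start.
    """

    def __init__(
        self,
        n_components: int = 4,
        n_starts: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
        var_floor: float = VAR_FLOOR_DEFAULT,
        random_state=None,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_obs, 2): columns [day_index, time_hours]")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X[:, 0].astype(int), X[:, 1]

    def fit(self, X, y=None):
        """Fit by multi-start EM.

        X is an (n_obs, 2) array whose columns are the day index and the
        timing in decimal hours (a DataFrame with those two columns in that
        order also works).
        """
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        day, t = self._validate(X)
        K = int(self.n_components)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if t.size < 10 * K:
            raise ValueError(f"need >= {10 * K} observations for K={K}, got {t.size}")
        self.days_, codes = np.unique(day, return_inverse=True)
        D = self.days_.size
        if D < 2:
            raise ValueError("need observations on >= 2 distinct days")
        rng = np.random.default_rng(self.random_state)

        best = None
        failures: list[str] = []
        for start in range(int(self.n_starts)):
            try:
                fitted = self._run_em(t, codes, D, K, start, rng)
            except _ComponentCollapse as exc:
                failures.append(f"start {start}: {exc}")
                continue
            if best is None or fitted["loglik"] > best["loglik"]:
                best = fitted
        if best is None:
            raise RuntimeError(
                f"all {self.n_starts} EM starts failed for K={K}: {failures}"
            )

        order = np.argsort(best["means"])
        self.means_ = best["means"][order]
        self.sds_ = np.sqrt(best["vars"][order])
        self.day_probs_ = best["pi"][:, order]
        self.responsibilities_ = best["resp"][:, order]
        self.loglik_ = best["loglik"]
        self.converged_ = best["converged"]
        self.n_iter_ = best["n_iter"]
        self.n_obs_ = t.size
        self.n_parameters_ = 2 * K + (K - 1) * D
        r = self.responsibilities_
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(r > 0, r * np.log(r), 0.0)))
        self.bic_ = -2.0 * self.loglik_ + self.n_parameters_ * np.log(self.n_obs_)
        self.icl_ = self.bic_ + 2.0 * self.entropy_
        # logit coefficients vs component 1: intercept = day-1 log-odds,
        # day-d coefficient = log-odds(day d) − log-odds(day 1)
        logodds = np.log(self.day_probs_[:, 1:] + 1e-300) - np.log(
            self.day_probs_[:, [0]] + 1e-300
        )  # (D, K-1)
        alpha = logodds.T.copy()  # (K-1, D): column 0 is the intercept day
        alpha[:, 1:] -= alpha[:, [0]]
        self.alpha_ = alpha
        return self

    # ------------------------------------------------------------------
    def _initial_params(self, t, codes, D, K, start, rng):
        n = t.size
        if start == 0:  # quantile start
            means = np.quantile(t, (np.arange(K) + 0.5) / K)
            var0 = max(np.var(t) / max(K, 1) ** 2, self.var_floor)
            vars_ = np.full(K, var0)
            pi = np.full((D, K), 1.0 / K)
            return means.astype(float), vars_, pi
        # random-responsibility start: one M-step from Dirichlet(1) rows
        resp = rng.dirichlet(np.ones(K), size=n)
        return self._m_step(t, codes, D, resp)

    def _m_step(self, t, codes, D, resp):
        n, K = resp.shape
        Nk = resp.sum(axis=0)
        if np.any(Nk < 1e-6 * n):
            raise _ComponentCollapse(f"component weight collapsed: {Nk.min():.3g}")
        means = resp.T @ t / Nk
        vars_ = np.maximum(
            (resp * (t[:, None] - means) ** 2).sum(axis=0) / Nk, self.var_floor
        )
        pi = np.zeros((D, K))
        np.add.at(pi, codes, resp)
        day_counts = pi.sum(axis=1, keepdims=True)
        pi = np.clip(pi / day_counts, 1e-12, None)
        pi /= pi.sum(axis=1, keepdims=True)
        return means, vars_, pi

    def _log_weights(self, t, codes, means, vars_, pi):
        logdens = -0.5 * (
            (t[:, None] - means) ** 2 / vars_ + np.log(2.0 * np.pi * vars_)
        )
        return np.log(pi)[codes] + logdens

    def _run_em(self, t, codes, D, K, start, rng):
        means, vars_, pi = self._initial_params(t, codes, D, K, start, rng)
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            logw = self._log_weights(t, codes, means, vars_, pi)
            ll_obs = logsumexp(logw, axis=1)
            ll = float(ll_obs.sum())
            # EM guarantees monotone log-likelihood; a real drop is a bug
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise AssertionError(
                    f"log-likelihood decreased: {prev_ll} -> {ll} at iter {n_iter}"
                )
            resp = np.exp(logw - ll_obs[:, None])
            if np.isfinite(prev_ll) and (ll - prev_ll) <= self.tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
            means, vars_, pi = self._m_step(t, codes, D, resp)
        if not converged:  # re-sync loglik/resp with the final M-step params
            logw = self._log_weights(t, codes, means, vars_, pi)
            ll_obs = logsumexp(logw, axis=1)
            ll = float(ll_obs.sum())
            resp = np.exp(logw - ll_obs[:, None])
        return dict(
            means=means, vars=vars_, pi=pi, resp=resp, loglik=ll,
            converged=converged, n_iter=n_iter,
        )

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Posterior component probabilities for (day_index, time) rows.

        Days unseen at fit time have no estimated π and raise KeyError.
        """
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        day, t = self._validate(X)
        lookup = {d: i for i, d in enumerate(self.days_)}
        try:
            codes = np.array([lookup[d] for d in day])
        except KeyError as exc:
            raise KeyError(f"day {exc} had no observations at fit time") from None
        logw = self._log_weights(t, codes, self.means_, self.sds_**2, self.day_probs_)
        return np.exp(logw - logsumexp(logw, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        """Most-probable component index per observation."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        day, t = self._validate(X)
        lookup = {d: i for i, d in enumerate(self.days_)}
        codes = np.array([lookup[d] for d in day])
        logw = self._log_weights(t, codes, self.means_, self.sds_**2, self.day_probs_)
        return float(np.mean(logsumexp(logw, axis=1)))


# ---------------------------------------------------------------------------
# module-level surface


def fit_em(X, K: int, n_starts: int = 5, random_state=None,
           tol: float = 1e-6, max_iter: int = 500) -> ConcomitantNormalMixture:
    """Fit a K-component day-indexed mixture (wrapper over the estimator)."""
    return ConcomitantNormalMixture(
        n_components=K, n_starts=n_starts, tol=tol, max_iter=max_iter,
        random_state=random_state,
    ).fit(X)


def icl_score(model: ConcomitantNormalMixture) -> float:
    """ICL of a fitted model: BIC plus twice the classification entropy."""
    return float(model.icl_)


def select_n_components(
    X,
    k_range=range(1, 9),
    n_starts: int = 5,
    random_state=None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ConcomitantNormalMixture:
    """Fit every K in ``k_range`` and return the ICL minimizer.

    The per-K score table is logged and attached to the winner as
    ``selection_table_`` (columns K, loglik, bic, icl, converged).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    fits: list[ConcomitantNormalMixture] = []
    rows = []
    for K in k_range:
        try:
            m = fit_em(X, K, n_starts=n_starts, random_state=random_state,
                       tol=tol, max_iter=max_iter)
        except (RuntimeError, ValueError) as exc:
            logger.warning("K=%d failed: %s", K, exc)
            continue
        fits.append(m)
        rows.append(dict(K=K, loglik=m.loglik_, bic=m.bic_, icl=m.icl_,
                         converged=m.converged_))
    if not fits:
        raise RuntimeError(f"every K in {k_range} failed to fit")
    table = pd.DataFrame(rows)
    logger.info("ICL selection table:\n%s", table.to_string(index=False))
    best = min(fits, key=lambda m: m.icl_)
    best.selection_table_ = table
    return best


@dataclass(frozen=True)
class ComponentSummary:
    """One mixture component with its protocol-slot assignment."""

    component_id: int
    mean_hours: float
    sd_hours: float
    avg_prob: float
    narrow: bool
    slot: str  # breakfast/lunch/dinner/bedtime/background/unassigned
    interval: tuple[float, float]  # mean ± 1.96 SD


def summarize_components(
    model: ConcomitantNormalMixture,
    sd_threshold: float = SD_THRESHOLD_DEFAULT,
    meal_times=MEAL_TIMES_DEFAULT,
) -> list[ComponentSummary]:
    """Classify fitted components into protocol slots.

    Components with SD below ``sd_threshold`` are *narrow*; when exactly
    four are narrow they are assigned, in time order, to the
    breakfast/lunch/dinner/bedtime slots (an adherent ward's signature).
    Any other narrow count leaves them ``unassigned`` (flagged in the log);
    wide components are ``background``.  ``avg_prob`` is the day-average
    mixing probability of the component.
    """
    avg_prob = model.day_probs_.mean(axis=0)
    narrow_idx = [k for k in range(model.n_components) if model.sds_[k] < sd_threshold]
    slots = {}
    if len(narrow_idx) == len(SLOT_NAMES):
        for name, k in zip(SLOT_NAMES, sorted(narrow_idx, key=lambda k: model.means_[k])):
            slots[k] = name
    elif narrow_idx:
        logger.warning(
            "%d narrow components (expected 4); slots left unassigned",
            len(narrow_idx),
        )
    out = []
    for k in range(model.n_components):
        narrow = k in narrow_idx
        slot = slots.get(k, "unassigned" if narrow else "background")
        mean, sd = float(model.means_[k]), float(model.sds_[k])
        out.append(
            ComponentSummary(k, mean, sd, float(avg_prob[k]), narrow, slot,
                             (mean - 1.96 * sd, mean + 1.96 * sd))
        )
    return out


def minutes_before(mean_hours: float, target_hours: float) -> int:
    """Signed whole minutes a component mean falls before a target time
    (positive = earlier than the target, negative = after)."""
    if not (0 <= mean_hours <= 24 and 0 <= target_hours <= 24):
        raise ValueError("hours must lie in [0, 24]")
    return int(round((target_hours - mean_hours) * 60.0))


def table2_summary(
    models: dict[str, ConcomitantNormalMixture],
    sd_threshold: float = SD_THRESHOLD_DEFAULT,
    meal_times=MEAL_TIMES_DEFAULT,
) -> pd.DataFrame:
    """Cross-ward component summary in the four-slot + background layout.

    For each protocol slot, the median (min, max) across wards of the
    component mean and SD; mixing probabilities are first day-averaged
    within each ward, then summarized.  All wide (SD ≥ threshold)
    components from all wards are pooled into a single ``background``
    column.  Wards lacking exactly four narrow components are skipped with
    a warning.
    """
    per_slot: dict[str, dict[str, list[float]]] = {
        s: {"mean": [], "sd": [], "prob": []} for s in SLOT_NAMES + ("background",)
    }
    used = 0
    for ward, model in models.items():
        summaries = summarize_components(model, sd_threshold, meal_times)
        narrow = [c for c in summaries if c.narrow]
        if len(narrow) != len(SLOT_NAMES):
            logger.warning("ward %s: %d narrow components, skipped from summary",
                           ward, len(narrow))
            continue
        used += 1
        for c in summaries:
            key = c.slot if c.slot in per_slot else "background"
            per_slot[key]["mean"].append(c.mean_hours)
            per_slot[key]["sd"].append(c.sd_hours)
            per_slot[key]["prob"].append(c.avg_prob)
    if used == 0:
        logger.warning("no ward had exactly four narrow components")
        return pd.DataFrame(
            columns=["slot", "quantity", "median", "min", "max", "n"]
        )
    rows = []
    for slot, vals in per_slot.items():
        for quantity in ("mean", "sd", "prob"):
            v = np.asarray(vals[quantity], dtype=float)
            if v.size == 0:
                continue
            rows.append(
                dict(slot=slot, quantity=quantity, median=float(np.median(v)),
                     min=float(v.min()), max=float(v.max()), n=int(v.size))
            )
    return pd.DataFrame(rows)


def model_to_dict(model: ConcomitantNormalMixture) -> dict:
    """JSON-serializable view of a fitted mixture (CLI output format)."""
    return dict(
        K=int(model.n_components),
        means=[float(v) for v in model.means_],
        sds=[float(v) for v in model.sds_],
        days=[int(d) for d in model.days_],
        day_probs=[[float(p) for p in row] for row in model.day_probs_],
        loglik=float(model.loglik_),
        bic=float(model.bic_),
        icl=float(model.icl_),
        entropy=float(model.entropy_),
        n_obs=int(model.n_obs_),
        converged=bool(model.converged_),
    )
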