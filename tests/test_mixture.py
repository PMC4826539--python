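"""Day-indexed concomitant mixture: EM correctness, ICL selection and the
component summaries."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import softmax

import glucotime as gt
from glucotime.mixture import (
    ConcomitantNormalMixture,
    minutes_before,
    select_n_components,
    summarize_components,
    table2_summary,
)


def _two_comp_data(rng, n=4000, means=(8.0, 20.0), sd=0.3, n_days=10):
    day = rng.integers(1, n_days + 1, n)
    comp = rng.integers(0, 2, n)
    t = rng.normal(np.asarray(means)[comp], sd)
    return np.column_stack([day, t]), comp


def test_k1_is_closed_form(rng):
    X, _ = _two_comp_data(rng, n=500)
    m = ConcomitantNormalMixture(n_components=1, n_starts=1).fit(X)
    assert m.means_[0] == pytest.approx(X[:, 1].mean(), abs=1e-9)
    assert m.sds_[0] == pytest.approx(X[:, 1].std(), abs=1e-6)
    assert np.allclose(m.day_probs_, 1.0)
    # zero entropy: ICL reduces to BIC with nu = 2 parameters
    assert m.entropy_ == pytest.approx(0.0, abs=1e-12)
    assert m.icl_ == pytest.approx(-2 * m.loglik_ + 2 * np.log(m.n_obs_))


def test_two_component_recovery(rng):
    X, _ = _two_comp_data(rng)
    m = ConcomitantNormalMixture(n_components=2, n_starts=3, random_state=0).fit(X)
    assert m.converged_
    np.testing.assert_allclose(m.means_, [8.0, 20.0], atol=0.05)
    np.testing.assert_allclose(m.sds_, 0.3, atol=0.05)


def test_hard_classification_makes_icl_equal_bic(rng):
    # components 40 SDs apart: responsibilities are effectively 0/1
    X, _ = _two_comp_data(rng, n=1000)
    m = ConcomitantNormalMixture(n_components=2, n_starts=2, random_state=0).fit(X)
    assert m.entropy_ == pytest.approx(0.0, abs=1e-6)
    assert m.icl_ == pytest.approx(m.bic_, abs=1e-5)


def test_responsibilities_normalized(rng):
    X, _ = _two_comp_data(rng, n=800, means=(9.0, 11.0))
    m = ConcomitantNormalMixture(n_components=2, n_starts=2, random_state=1).fit(X)
    np.testing.assert_allclose(m.responsibilities_.sum(axis=1), 1.0, atol=1e-10)
    np.testing.assert_allclose(m.day_probs_.sum(axis=1), 1.0, atol=1e-10)
    proba = m.predict_proba(X[:50])
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-10)


def test_saturated_logit_m_step_matches_iterative_fit(rng):
    """The closed-form concomitant M-step (per-day responsibility means)
    equals a numerically maximized multinomial logit on day indicators."""
    X, _ = _two_comp_data(rng, n=120, means=(9.0, 14.0), n_days=3)
    m = ConcomitantNormalMixture(n_components=2, n_starts=2, random_state=0).fit(X)
    resp = m.responsibilities_
    codes = np.searchsorted(m.days_, X[:, 0].astype(int))
    D, K = m.days_.size, 2

    def neg_q(theta):  # logits for components 2..K per day, alpha_1 = 0
        logits = np.zeros((D, K))
        logits[:, 1:] = theta.reshape(D, K - 1)
        pi = softmax(logits, axis=1)
        return -np.sum(resp * np.log(pi[codes] + 1e-300))

    res = minimize(neg_q, np.zeros(D * (K - 1)), method="BFGS")
    pi_opt = softmax(
        np.column_stack([np.zeros(D), res.x.reshape(D, K - 1)]), axis=1
    )
    np.testing.assert_allclose(m.day_probs_, pi_opt, atol=1e-6)


def test_em_requires_minimum_data(rng):
    X = np.column_stack([np.r_[np.ones(8), 2 * np.ones(7)], rng.uniform(0, 24, 15)])
    with pytest.raises(ValueError):
        ConcomitantNormalMixture(n_components=2).fit(X)
    single_day = np.column_stack([np.ones(50), rng.uniform(0, 24, 50)])
    with pytest.raises(ValueError, match="2 distinct days"):
        ConcomitantNormalMixture(n_components=2).fit(single_day)


def test_day_varying_probabilities_recovered(rng):
    # two components whose mix flips between the two halves of the window
    n_days, per_day = 10, 150
    rows = []
    for d in range(1, n_days + 1):
        p0 = 0.8 if d <= 5 else 0.2
        comp = rng.random(per_day) > p0
        t = rng.normal(np.where(comp, 20.0, 8.0), 0.3)
        rows.append(np.column_stack([np.full(per_day, d), t]))
    X = np.vstack(rows)
    m = ConcomitantNormalMixture(n_components=2, n_starts=3, random_state=0).fit(X)
    first_half = m.day_probs_[:5, 0].mean()
    second_half = m.day_probs_[5:, 0].mean()
    assert first_half == pytest.approx(0.8, abs=0.05)
    assert second_half == pytest.approx(0.2, abs=0.05)
    # alpha is the day-wise log-odds against component 1
    expected_logodds = np.log(m.day_probs_[:, 1] / m.day_probs_[:, 0])
    recovered = m.alpha_[0].copy()
    recovered[1:] += recovered[0]
    np.testing.assert_allclose(recovered, expected_logodds, atol=1e-8)


def test_select_k_prefers_single_gaussian(rng):
    n = 600
    X = np.column_stack([rng.integers(1, 6, n), rng.normal(12.0, 1.0, n)])
    best = select_n_components(X, k_range=range(1, 4), n_starts=2, random_state=0)
    assert best.n_components == 1
    assert list(best.selection_table_["K"]) == [1, 2, 3]


def test_select_k_empty_range():
    with pytest.raises(ValueError):
        select_n_components(np.zeros((10, 2)), k_range=[])


def test_table2_style_ward_recovers_four_narrow_components(table2_ward):
    panel, truth, spec = table2_ward
    X = panel.to_frame()[["day_index", "time_hours"]].to_numpy()
    best = select_n_components(X, k_range=range(2, 7), n_starts=3, random_state=0)
    summaries = summarize_components(best)
    narrow = [c for c in summaries if c.narrow]
    assert len(narrow) == 4
    slots = [c.slot for c in sorted(narrow, key=lambda c: c.mean_hours)]
    assert slots == ["breakfast", "lunch", "dinner", "bedtime"]
    means = sorted(c.mean_hours for c in narrow)
    np.testing.assert_allclose(means, spec.means, atol=0.1)
    # ICL prefers the 4-or-5 component truth over a 2-component collapse
    table = best.selection_table_.set_index("K")["icl"]
    assert min(table.get(4, np.inf), table.get(5, np.inf)) < table[2]


def test_summaries_invariant_to_component_relabelling(table2_ward):
    panel, _, _ = table2_ward
    X = panel.to_frame()[["day_index", "time_hours"]].to_numpy()
    a = gt.fit_em(X, 5, n_starts=2, random_state=0)
    b = gt.fit_em(X, 5, n_starts=3, random_state=99)
    sa = [(c.slot, round(c.mean_hours, 2)) for c in summarize_components(a)]
    sb = [(c.slot, round(c.mean_hours, 2)) for c in summarize_components(b)]
    assert sa == sb


def test_slot_assignment_rules():
    m = ConcomitantNormalMixture(n_components=4)
    m.means_ = np.array([7.2, 11.4, 17.2, 21.9])
    m.sds_ = np.array([0.3, 0.3, 0.3, 0.3])
    m.day_probs_ = np.full((5, 4), 0.25)
    slots = [c.slot for c in summarize_components(m)]
    assert slots == ["breakfast", "lunch", "dinner", "bedtime"]
    m.sds_ = np.array([0.3, 0.3, 0.3, 1.5])  # only 3 narrow components
    summaries = summarize_components(m)
    assert [c.slot for c in summaries] == ["unassigned"] * 3 + ["background"]


@pytest.mark.parametrize(
    "mean, target, minutes",
    [
        (7.23, 8.0, 46), (6.29, 8.0, 103), (7.52, 8.0, 29),
        (11.38, 12.0, 37), (11.11, 12.0, 53), (11.61, 12.0, 23),
        (17.18, 18.0, 49), (17.02, 18.0, 59), (17.37, 18.0, 38),
        (21.94, 22.0, 4), (21.57, 22.0, 26), (22.26, 22.0, -16),
    ],
)
def test_minutes_before_target(mean, target, minutes):
    assert minutes_before(mean, target) == minutes


def test_table2_summary_single_ward_degenerates(table2_ward):
    panel, _, _ = table2_ward
    X = panel.to_frame()[["day_index", "time_hours"]].to_numpy()
    model = gt.fit_em(X, 5, n_starts=2, random_state=0)
    table = table2_summary({"W01": model})
    means = table[(table.quantity == "mean")]
    assert (means["median"] == means["min"]).all()
    assert (means["median"] == means["max"]).all()
    # probabilities are day-averaged within the ward first
    probs = table[table.quantity == "prob"].set_index("slot")
    assert probs.loc["breakfast", "median"] == pytest.approx(
        model.day_probs_.mean(axis=0)[np.argmin(np.abs(model.means_ - 7.23))], abs=1e-9
    )


def test_table2_summary_no_narrow_components_warns(caplog):
    m = ConcomitantNormalMixture(n_components=2)
    m.means_ = np.array([9.0, 15.0])
    m.sds_ = np.array([3.0, 4.0])
    m.day_probs_ = np.full((4, 2), 0.5)
    table = table2_summary({"W01": m})
    assert table.empty
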