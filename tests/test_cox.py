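"""Cox core: partial likelihood, Newton fit, Breslow baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icusurv.cox import (
    BaselineSurvival,
    ConvergenceError,
    breslow_baseline,
    cox_partial_log_likelihood,
    cox_partial_loglik_gradient,
    fit_linear_cox,
    survival_function,
)


def test_equal_risk_all_events_closed_form():
    # three subjects, distinct times, all events, scores 0: -ln 3! = -ln 6
    ll = cox_partial_log_likelihood([0, 0, 0], [1, 2, 3], [1, 1, 1])
    assert ll == pytest.approx(-np.log(6), abs=1e-12)


def test_breslow_tied_event_matches_hand_expansion(rng):
    # five subjects; two deaths tied at t=1, one at t=2, censored at 3, death at 4
    s = rng.normal(size=5)
    times = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 0, 1])
    e = np.exp(s)
    hand = (
        s[0] + s[1] - 2 * np.log(e.sum())
        + s[2] - np.log(e[2:].sum())
        + s[4] - np.log(e[4])
    )
    assert cox_partial_log_likelihood(s, times, events) == pytest.approx(hand, rel=1e-12)


@settings(deadline=None, max_examples=25)
@given(shift=st.floats(-40, 40))
def test_partial_likelihood_shift_invariance(shift):
    rng = np.random.default_rng(5)
    s = rng.normal(size=12)
    t = rng.exponential(size=12) + 0.01
    e = rng.uniform(size=12) < 0.7
    if e.sum() == 0:
        e[0] = True
    a = cox_partial_log_likelihood(s, t, e)
    b = cox_partial_log_likelihood(s + shift, t, e)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_partial_likelihood_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="no events"):
        cox_partial_log_likelihood([0.0, 0.0], [1.0, 2.0], [0, 0])
    with pytest.raises(ValueError, match="non-finite"):
        cox_partial_log_likelihood([np.inf, 0.0], [1.0, 2.0], [1, 1])


def test_gradient_matches_central_differences():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(5, 50))
        s = rng.normal(size=n)
        t = rng.exponential(size=n) + 0.01
        if rng.random() < 0.5:  # inject ties
            t = np.round(t, 1) + 0.05
        e = rng.uniform(size=n) < 0.6
        if e.sum() == 0:
            e[int(rng.integers(n))] = True
        g = cox_partial_loglik_gradient(s, t, e)
        h = 1e-6
        fd = np.empty(n)
        for i in range(n):
            up, dn = s.copy(), s.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = (
                cox_partial_log_likelihood(up, t, e)
                - cox_partial_log_likelihood(dn, t, e)
            ) / (2 * h)
        scale = max(1.0, np.abs(fd).max())
        assert np.abs(g - fd).max() / scale < 1e-6


def test_fit_rejects_zero_variance_column():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 1])
    X = np.column_stack([np.ones(4), [0.1, 0.5, -0.3, 0.2]])
    with pytest.raises(ValueError, match="zero variance"):
        fit_linear_cox(X, t, e)


def test_fit_matches_grid_search_on_tiny_problem():
    # one binary covariate, four subjects: brute-force maximize the partial
    # likelihood over a grid, refine, compare to the Newton fit
    X = np.array([[1.0], [0.0], [1.0], [0.0]])
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 1])
    fit = fit_linear_cox(X, t, e)
    coarse = np.linspace(-5, 5, 2001)
    lls = [cox_partial_log_likelihood(X[:, 0] * b, t, e) for b in coarse]
    b0 = coarse[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 4001)
    lls = [cox_partial_log_likelihood(X[:, 0] * b, t, e) for b in fine]
    assert fit.coefficients[0] == pytest.approx(fine[int(np.argmax(lls))], abs=1e-4)


def test_fit_agrees_with_lifelines_reference():
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    rng = np.random.default_rng(3)
    n = 300
    X = rng.normal(size=(n, 3))
    beta = np.array([0.5, -0.4, 0.0])
    t = rng.exponential(1 / np.exp(X @ beta))
    e = rng.uniform(size=n) < 0.75
    fit = fit_linear_cox(X, t, e)
    df = pd.DataFrame(X, columns=list("abc"))
    df["T"], df["E"] = t, e.astype(int)
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.coefficients, ref.params_.values, atol=5e-5)
    np.testing.assert_allclose(fit.standard_errors, ref.standard_errors_.values, atol=5e-4)


def test_efron_ties_agree_with_lifelines():
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    rng = np.random.default_rng(4)
    n = 150
    X = rng.normal(size=(n, 2))
    t = np.ceil(rng.exponential(3 / np.exp(X @ [0.6, -0.2]), size=n))  # heavy ties
    e = rng.uniform(size=n) < 0.7
    fit = fit_linear_cox(X, t, e, ties="efron")
    df = pd.DataFrame(X, columns=list("ab"))
    df["T"], df["E"] = t, e.astype(int)
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron
    np.testing.assert_allclose(fit.coefficients, ref.params_.values, atol=1e-4)


def test_fit_flags_separation():
    # the only covariate perfectly orders deaths before censorings
    X = np.array([[1.0], [1.0], [0.0], [0.0], [0.0]])
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([1, 1, 0, 0, 0])
    with pytest.raises(ConvergenceError) as exc:
        fit_linear_cox(X, t, e)
    assert exc.value.last_beta is not None


def test_model_invariants_on_fit(small_cohort):
    X = small_cohort.design_matrix()
    fit = fit_linear_cox(X, small_cohort.times, small_cohort.events)
    np.testing.assert_allclose(fit.hazard_ratios, np.exp(fit.coefficients))
    assert np.all(fit.ci_lower < fit.hazard_ratios)
    assert np.all(fit.hazard_ratios < fit.ci_upper)
    assert fit.convergence_info["final_gradient_norm"] < 1e-8


def test_breslow_baseline_single_event_closed_form():
    n = 7
    scores = np.zeros(n)
    times = np.arange(1.0, n + 1)
    events = np.zeros(n, dtype=int)
    events[0] = 1  # earliest subject dies, everyone at risk
    base = breslow_baseline(scores, times, events)
    assert base.at(0.5) == 1.0  # before the first event
    assert base.at(1.0) == pytest.approx(np.exp(-1 / n), rel=1e-12)


def test_baseline_monotone_nonincreasing(small_cohort):
    base = breslow_baseline(
        np.zeros(len(small_cohort)), small_cohort.times, small_cohort.events
    )
    assert np.all(np.diff(base.s0) <= 1e-15)
    assert np.all((base.s0 > 0) & (base.s0 <= 1))


def test_survival_function_power_relation(small_cohort):
    base = breslow_baseline(
        np.zeros(len(small_cohort)), small_cohort.times, small_cohort.events
    )
    identity = survival_function(base, 0.0)
    np.testing.assert_allclose(identity.values, base.s0)
    # doubling exp(psi) squares the curve pointwise
    a = survival_function(base, np.log(1.0)).values
    b = survival_function(base, np.log(2.0)).values
    np.testing.assert_allclose(b, a**2, rtol=1e-12)
    assert np.all(np.diff(b) <= 1e-15)


def test_no_event_baseline_gives_unit_curve():
    base = BaselineSurvival(times=np.array([]), s0=np.array([]))
    curve = survival_function(base, 2.7)
    assert curve.at(123.0) == 1.0


def test_concordance_ordering_preserved_under_hazard_scaling(small_cohort):
    base = breslow_baseline(
        np.zeros(len(small_cohort)), small_cohort.times, small_cohort.events
    )
    t_grid = base.times
    s1 = survival_function(base, 0.3).at(t_grid)
    s2 = survival_function(base, 1.1).at(t_grid)
    # multiplying all exp(psi) by a constant preserves curve ordering
    s1c = survival_function(base, 0.3 + np.log(3)).at(t_grid)
    s2c = survival_function(base, 1.1 + np.log(3)).at(t_grid)
    assert np.all((s1 >= s2) == (s1c >= s2c))
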