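"""Kaplan-Meier, log-rank, Cox and PH-assumption unit tests.

The independent oracles here are lifelines (log-rank, Cox coefficients)
and a brute-force grid maximization of the Efron log partial likelihood
written directly from the formula.
"""

import numpy as np
import pytest

import kmcut
from kmcut.exceptions import (
    ConstantVariableError,
    InsufficientEventsError,
    NoEventsWarning,
    NonConvergenceError,
    SmallSampleWarning,
)
from tests.conftest import random_survival


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_no_censoring():
    c = kmcut.km_estimate([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(c.at_risk, [3, 2, 1])


def test_km_censoring_reduces_risk_set():
    c = kmcut.km_estimate([1, 2], [1, 0])
    np.testing.assert_allclose(c.event_times, [1])
    np.testing.assert_allclose(c.survival, [0.5])
    np.testing.assert_allclose(c.censoring_times, [2])


def test_km_all_censored_warns():
    with pytest.warns(NoEventsWarning):
        c = kmcut.km_estimate([1, 2, 3], [0, 0, 0])
    assert c.event_times.size == 0
    assert c.survival_at(2.0) == 1.0


def test_km_matches_empirical_without_censoring(rng):
    t = rng.exponential(5.0, size=200)
    c = kmcut.km_estimate(t, np.ones(200, dtype=int))
    for q in [1.0, 3.0, 8.0]:
        assert c.survival_at(q) == pytest.approx((t > q).mean())


def test_km_monotone_and_right_continuous(rng):
    t, e, _ = random_survival(rng, 150)
    c = kmcut.km_estimate(t, e)
    assert np.all(np.diff(c.survival) <= 1e-15)
    assert c.survival[0] <= 1.0
    assert np.all(np.diff(c.at_risk) < 0)
    # right continuity: value at an event time equals the post-drop value
    assert c.survival_at(c.event_times[0]) == pytest.approx(c.survival[0])


def test_median_survival_conventions():
    c = kmcut.km_estimate([1, 2, 3], [1, 1, 1])
    assert c.median_survival() == (2.0, "median")
    # S hits exactly 0.5 -> inclusive boundary
    c2 = kmcut.km_estimate([10, 10, 20, 20], [1, 1, 0, 0])
    assert c2.survival[0] == pytest.approx(0.5)
    assert c2.median_survival() == (10.0, "median")


def test_median_falls_back_to_upper_quartile():
    # one event among five -> curve floors at 0.8: no median; S<=0.75 never
    c = kmcut.km_estimate([1, 2, 3, 4, 5], [1, 0, 0, 0, 0])
    assert c.median_survival() == (None, "undefined")
    # two events among five: floor 0.6 -> upper-quartile defined at 2nd event
    c2 = kmcut.km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])
    t, kind = c2.median_survival()
    assert kind == "upper_quartile" and t == 2.0


def test_survival_at_step_function():
    c = kmcut.km_estimate([1, 2, 3], [1, 1, 1])
    assert c.survival_at(0) == 1.0
    assert c.survival_at(2.5) == pytest.approx(1 / 3)
    assert c.survival_at(99) == 0.0
    with pytest.raises(ValueError):
        kmcut.survival_at(c, -1)


# ---------------------------------------------------------------------------
# log-rank

def test_logrank_identical_groups_null():
    t = np.array([1, 1, 2, 2, 3, 3], dtype=float)
    e = np.ones(6, dtype=int)
    g = np.array([0, 1, 0, 1, 0, 1])
    chi2, p = kmcut.logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank
    rng = np.random.default_rng(7)
    for _ in range(10):
        t, e, g = random_survival(rng, 80, hr=1.7)
        t = np.round(t, 1)  # induce ties
        if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
            continue
        chi2, p = kmcut.logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)


def test_logrank_agrees_with_cox_score():
    """The Breslow score test at beta=0 is algebraically the log-rank
    statistic; the two must correlate essentially perfectly."""
    rng = np.random.default_rng(11)
    lr, sc = [], []
    for _ in range(30):
        t, e, g = random_survival(rng, 1000, hr=rng.uniform(0.7, 1.5))
        chi2, _ = kmcut.logrank_test(t, e, g)
        s, _ = kmcut.cox_score_test(t, e, g.astype(float), ties="breslow")
        lr.append(chi2)
        sc.append(s)
    assert np.corrcoef(lr, sc)[0, 1] > 0.99


def test_logrank_requires_two_groups():
    from kmcut.exceptions import DegenerateGroupError
    with pytest.raises(DegenerateGroupError):
        kmcut.logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])


# ---------------------------------------------------------------------------
# Cox regression

def efron_loglik_grid(time, event, x, grid):
    """Independent brute-force Efron log partial likelihood over a beta
    grid, written straight from the definition (evaluated for the whole
    grid at once, one event time at a time)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    W = np.exp(np.outer(x, grid))          # (n, n_grid)
    lls = np.zeros(grid.size)
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = int(dead.sum())
        s0r = W[risk].sum(axis=0)
        s0d = W[dead].sum(axis=0)
        lls += x[dead].sum() * grid
        for ell in range(d):
            lls -= np.log(s0r - (ell / d) * s0d)
    return lls


def test_cox_symmetry_gives_null_beta():
    t = np.array([1, 1, 2, 2, 3, 3, 4, 4], dtype=float)
    e = np.array([1, 1, 1, 1, 0, 0, 1, 1])
    g = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    with pytest.warns(SmallSampleWarning):
        fit = kmcut.cox_fit(t, e, g)
    assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_cox_matches_grid_search(seed):
    rng = np.random.default_rng(seed)
    t, e, g = random_survival(rng, 25, hr=2.0)
    if e.sum() < 3 or g.std() == 0:
        pytest.skip("degenerate draw")
    grid = np.arange(-5, 5, 1e-4)
    lls = efron_loglik_grid(t, e, g.astype(float), grid)
    try:
        fit = kmcut.cox_fit(t, e, g.astype(float), warn_small=False)
    except NonConvergenceError:
        # monotone likelihood: the grid maximum must sit on the boundary
        assert np.argmax(lls) in (0, grid.size - 1)
        return
    assert fit.coefficients[0] == pytest.approx(grid[np.argmax(lls)],
                                                abs=1e-3)


def test_cox_matches_lifelines_multivariate():
    import pandas as pd
    from lifelines import CoxPHFitter
    rng = np.random.default_rng(3)
    n = 300
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x1 - 0.3 * x2)))
    e = (t <= rng.exponential(30, size=n)).astype(int)
    t = np.minimum(t, 60)
    fit = kmcut.cox_fit(t, e, np.column_stack([x1, x2]), names=["x1", "x2"])
    ref = CoxPHFitter().fit(
        pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2}), "t", "e")
    np.testing.assert_allclose(fit.coefficients,
                               ref.params_[["x1", "x2"]].values, atol=1e-6)
    np.testing.assert_allclose(fit.se,
                               ref.standard_errors_[["x1", "x2"]].values,
                               atol=1e-6)


def test_cox_breslow_ties_option():
    t = np.array([1, 1, 1, 2, 2, 3, 4, 5] * 5, dtype=float)
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1] * 5)
    rng = np.random.default_rng(0)
    x = rng.normal(size=t.size)
    fe = kmcut.cox_fit(t, e, x, ties="efron")
    fb = kmcut.cox_fit(t, e, x, ties="breslow")
    assert fe.ties_method == "efron" and fb.ties_method == "breslow"
    assert fe.coefficients[0] != fb.coefficients[0]


def test_cox_perfect_separation_raises():
    # all events in the high group, all low-group subjects censored later
    t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
    e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    g = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    with pytest.raises(NonConvergenceError) as exc:
        kmcut.cox_fit(t, e, g, warn_small=False)
    assert exc.value.direction is not None


def test_cox_small_sample_warning(example10):
    grp = (example10.marker("ABC123") > 3638.0).astype(float)  # median split
    with pytest.warns(SmallSampleWarning):
        kmcut.cox_fit(example10.time, example10.event, grp)


def test_cox_infinite_hr_on_example_table(example10):
    """The 10-sample example table's Gene_1 median split concentrates the
    informative events in one cohort: the partial likelihood is monotone
    and the fit must report the infinite-HR direction."""
    grp = (example10.marker("Gene_1") > 2653.0).astype(float)
    with pytest.raises(NonConvergenceError) as exc:
        kmcut.cox_fit(example10.time, example10.event, grp, warn_small=False)
    assert exc.value.direction is not None


def test_cox_constant_covariate():
    with pytest.raises(ConstantVariableError):
        kmcut.cox_fit([1, 2, 3, 4], [1, 1, 0, 1], np.ones(4),
                      warn_small=False)


# ---------------------------------------------------------------------------
# HR inversion

def test_invert_hr_reciprocal():
    rng = np.random.default_rng(5)
    t, e, g = random_survival(rng, 200, hr=0.4)
    fit = kmcut.cox_fit(t, e, g.astype(float))
    assert fit.hr[0] < 1
    inv = kmcut.invert_hr(fit)
    assert inv.hr[0] == pytest.approx(1 / fit.hr[0])
    assert inv.ci_low[0] == pytest.approx(1 / fit.ci_high[0])
    assert inv.ci_high[0] == pytest.approx(1 / fit.ci_low[0])
    assert inv.p[0] == fit.p[0]
    assert inv.global_p == fit.global_p


def test_invert_hr_noop_above_one():
    rng = np.random.default_rng(6)
    t, e, g = random_survival(rng, 200, hr=2.5)
    fit = kmcut.cox_fit(t, e, g.astype(float))
    assert fit.hr[0] > 1
    assert kmcut.invert_hr(fit) is fit


def test_invert_hr_involution():
    rng = np.random.default_rng(7)
    t, e, g = random_survival(rng, 200, hr=0.5)
    fit = kmcut.cox_fit(t, e, g.astype(float))
    twice = kmcut.invert_hr(kmcut.invert_hr(fit))
    assert twice.hr[0] == pytest.approx(kmcut.invert_hr(fit).hr[0])
    # inverting an already-inverted (>1) result is a no-op
    assert twice.inverted == kmcut.invert_hr(fit).inverted


# ---------------------------------------------------------------------------
# proportional-hazards assumption test

def test_ph_single_covariate_global_equals_marginal(rng):
    t, e, g = random_survival(rng, 300, hr=2.0)
    fit = kmcut.cox_fit(t, e, g.astype(float))
    ph = kmcut.ph_assumption_test(fit)
    assert ph.p[0] == pytest.approx(ph.global_p, rel=1e-9)
    assert 0 <= ph.global_p <= 1


def test_ph_matches_lifelines_km_transform():
    import pandas as pd
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test
    rng = np.random.default_rng(13)
    t, e, g = random_survival(rng, 400, hr=2.0)
    fit = kmcut.cox_fit(t, e, g.astype(float))
    ph = kmcut.ph_assumption_test(fit)
    df = pd.DataFrame({"t": t, "e": e, "g": g})
    cph = CoxPHFitter().fit(df, "t", "e")
    ref = proportional_hazard_test(cph, df, time_transform="km")
    ref_stat = float(np.asarray(ref.test_statistic).ravel()[0])
    assert ph.chi2[0] == pytest.approx(ref_stat, rel=0.02)


def test_ph_too_few_events():
    t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    e = np.array([1, 1, 0, 0, 0, 0])
    x = np.array([0.1, 0.9, 0.2, 0.8, 0.3, 0.7])
    fit = kmcut.cox_fit(t, e, x, warn_small=False)
    with pytest.raises(InsufficientEventsError):
        kmcut.ph_assumption_test(fit)
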