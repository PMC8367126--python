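"""Quantile cutoffs, trichotomization, the best-cutoff scan and BH FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kmcut
from kmcut.cutoffs import HIGH, LOW, OMITTED
from kmcut.exceptions import ConstantVariableError, ScanFailedError
from kmcut.simulate import FixtureSpec, generate


# ---------------------------------------------------------------------------
# quantiles & dichotomization

def test_quantile_cutoff_examples(example10):
    assert kmcut.quantile_cutoff([1, 2, 3, 4, 5], 0.5) == 3
    assert kmcut.quantile_cutoff([1, 2, 3, 4], 0.25) == pytest.approx(1.75)
    # hand-computed median of the example Gene_1 column:
    # sorted 19,1209,1441,1894,2529,2777,2977,3064,3573,4606 -> 2653
    assert kmcut.quantile_cutoff(example10.marker("Gene_1"), 0.5) == 2653.0


def test_quantile_cutoff_errors():
    with pytest.raises(ConstantVariableError):
        kmcut.quantile_cutoff([2, 2, 2, 2], 0.5)
    with pytest.raises(ValueError):
        kmcut.quantile_cutoff([1, 2, 3], 0.5)


def test_dichotomize_boundary_is_low():
    labels = kmcut.dichotomize([1, 2, 3], 2)
    assert list(labels) == [LOW, LOW, HIGH]
    assert set(kmcut.dichotomize([1, 2, 3], 0.5)) == {HIGH}
    assert set(kmcut.dichotomize([1, 2, 3], 3)) == {LOW}


def test_trichotomize_exact_tertiles():
    labels, q1, q2 = kmcut.trichotomize(np.arange(1, 10))
    assert list(labels[:3]) == [LOW] * 3
    assert list(labels[3:6]) == [OMITTED] * 3
    assert list(labels[6:]) == [HIGH] * 3


def test_trichotomize_heavy_ties_deterministic():
    vals = np.array([1, 1, 1, 1, 2, 2, 5, 5, 9, 9], dtype=float)
    labels, q1, q2 = kmcut.trichotomize(vals)
    # the <=/> rule is applied deterministically at the tied boundaries
    assert list(labels) == list(kmcut.trichotomize(vals)[0])
    assert (labels == LOW).sum() + (labels == HIGH).sum() + \
        (labels == OMITTED).sum() == 10
    with pytest.raises(ConstantVariableError):
        kmcut.trichotomize(np.ones(8))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def brute_force_bh(p):
    """Step-up definition, written independently: q_i = min over j with
    p_(j) >= p_(i) of p_(j) * n / rank(j), clipped at 1."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        q[i] = running
    return q


def test_bh_examples():
    np.testing.assert_allclose(kmcut.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(kmcut.bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(kmcut.bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_brute_force(pvals):
    np.testing.assert_allclose(kmcut.bh_adjust(pvals), brute_force_bh(pvals),
                               atol=1e-12)


def test_bh_nan_passthrough():
    q = kmcut.bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and np.isfinite(q[0])
    # the NaN does not count toward the number of tests
    np.testing.assert_allclose(q[[0, 2]], kmcut.bh_adjust([0.01, 0.5]))


# ---------------------------------------------------------------------------
# best-cutoff scan

@pytest.fixture(scope="module")
def scan_fixture():
    ds, _ = generate(FixtureSpec(n=120, true_hr=(2.5,),
                                 censoring_fraction=0.2, seed=42))
    return ds


def test_scan_candidate_set_definition(scan_fixture):
    ds = scan_fixture
    vals = ds.marker("Marker_1")
    scan = kmcut.best_cutoff_scan(vals, ds.time, ds.event)
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    expected = np.unique(vals)
    expected = expected[(expected >= q1) & (expected <= q3)]
    np.testing.assert_allclose(scan.candidates, expected)
    assert q1 <= scan.best_cutoff <= q3
    # both cohorts at every candidate hold at least a quarter of the cohort
    assert scan.n_low[scan.best_index] >= 0.25 * ds.n
    assert scan.n_high[scan.best_index] >= 0.25 * ds.n


def test_scan_best_is_minimum_p(scan_fixture):
    ds = scan_fixture
    scan = kmcut.best_cutoff_scan(ds.marker("Marker_1"), ds.time, ds.event)
    assert scan.best_p == np.nanmin(scan.p)
    assert len(scan.p) == len(scan.hr) == len(scan.q) == len(scan.candidates)


def test_scan_median_candidate_consistency(scan_fixture):
    """The scan's p at the median split equals a direct median-split Cox."""
    ds = scan_fixture
    vals = ds.marker("Marker_1")
    scan = kmcut.best_cutoff_scan(vals, ds.time, ds.event)
    med = kmcut.quantile_cutoff(vals, 0.5)
    # the largest candidate <= the interpolated median gives the same split
    cand = scan.candidates[scan.candidates <= med].max()
    i = int(np.nonzero(scan.candidates == cand)[0][0])
    grp = (vals > cand).astype(float)
    direct = kmcut.invert_hr(
        kmcut.cox_fit(ds.time, ds.event, grp, warn_small=False))
    assert scan.p[i] == pytest.approx(direct.p[0], rel=1e-12)
    assert scan.hr[i] == pytest.approx(direct.hr[0], rel=1e-12)


def test_scan_min_p_beats_fixed_quantiles(scan_fixture):
    ds = scan_fixture
    vals = ds.marker("Marker_1")
    scan = kmcut.best_cutoff_scan(vals, ds.time, ds.event)
    for q in (0.25, 0.5, 0.75):
        cut = kmcut.quantile_cutoff(vals, q)
        cand = scan.candidates[scan.candidates <= cut]
        if cand.size == 0:
            continue
        grp = (vals > cand.max()).astype(float)
        fit = kmcut.cox_fit(ds.time, ds.event, grp, warn_small=False)
        assert scan.best_p <= fit.p[0] + 1e-12


def test_scan_hr_inverted_to_at_least_one(scan_fixture):
    ds = scan_fixture
    scan = kmcut.best_cutoff_scan(ds.marker("Marker_1"), ds.time, ds.event)
    assert np.all(scan.hr[np.isfinite(scan.hr)] >= 1.0)


def test_scan_perfect_separation_reported_per_candidate():
    # marker value order identical to event-time order: early events vs
    # late censoring separate cleanly somewhere inside the IQR
    n = 24
    vals = np.arange(n, dtype=float)
    time = np.concatenate([np.arange(1, n // 2 + 1),
                           np.full(n // 2, 100.0)])
    event = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
    scan = kmcut.best_cutoff_scan(vals, time, event)
    # every candidate is recorded: converged ones with finite p, perfectly
    # separating ones as NaN
    assert len(scan.p) == len(scan.candidates)
    assert np.isnan(scan.p).any()
    assert np.isfinite(scan.best_p)


def test_scan_needs_events():
    with pytest.raises(ScanFailedError):
        kmcut.best_cutoff_scan(np.arange(10.0), np.arange(1, 11.0),
                               np.zeros(10, int))


def test_cutoff_plot_data_roundtrip(scan_fixture):
    import json
    ds = scan_fixture
    scan = kmcut.best_cutoff_scan(ds.marker("Marker_1"), ds.time, ds.event)
    data = kmcut.cutoff_plot_data(scan)
    assert len(data["cutoff"]) == len(data["p"]) == len(data["hr"])
    assert data["best"]["cutoff"] == scan.best_cutoff
    assert data["best"]["p"] == scan.best_p
    parsed = json.loads(json.dumps(data))
    assert parsed["cutoff"] == data["cutoff"]
    assert parsed["best"] == data["best"]
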