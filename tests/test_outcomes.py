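"""Outcome resolution, progression arithmetic, survival and FDR correction.

Survival and FDR results are cross-checked against hand computations:
an explicit product-limit table, an observed-minus-expected log-rank
table, and a direct enumeration of the Benjamini-Hochberg step-up rule.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsindex import outcomes as oc


def _visits(sid, *triples):
    """triples: (month, diagnosis, vital)"""
    return pd.DataFrame(
        {"subject_id": sid, "month": [t[0] for t in triples],
         "diagnosis": [t[1] for t in triples], "mmse": 28, "cdr_sob": 0.0,
         "vital_status": [t[2] if len(t) > 2 else "alive" for t in triples]})


class TestFinalOutcome:
    def test_progression_to_mci_at_recorded_visit(self):
        o = oc.final_outcome(_visits("a", (0, "SMD"), (18, "SMD"), (36, "MCI")))
        assert (o.outcome, o.month, o.is_event) == ("MCI", 36.0, True)

    def test_reversion_to_hc_is_not_an_event(self):
        o = oc.final_outcome(_visits("a", (0, "SMD"), (18, "HC")))
        assert (o.outcome, o.month, o.is_event) == ("HC", 18.0, False)

    def test_death_recorded_at_its_visit(self):
        o = oc.final_outcome(_visits("a", (0, "SMD"), (18, "SMD"),
                                     (54, "SMD", "died")))
        assert (o.outcome, o.month, o.is_event) == ("died", 54.0, True)

    def test_death_precedes_later_progression(self):
        o = oc.final_outcome(_visits("a", (0, "HC"), (18, "HC", "died"),
                                     (36, "MCI")))
        assert o.outcome == "died" and o.month == 18.0

    def test_baseline_only_is_missing(self):
        o = oc.final_outcome(_visits("a", (0, "HC")))
        assert (o.outcome, o.is_event) == ("missing", False)

    def test_stable_censored_at_last_attended_visit(self):
        o = oc.final_outcome(_visits("a", (0, "MCI"), (18, "MCI"), (54, "MCI")))
        assert (o.outcome, o.month, o.is_event) == ("MCI", 54.0, False)


def test_outcome_table_reproduces_reference_counts():
    fu, groups = oc.followup_from_counts(oc.REFERENCE_OUTCOME_COUNTS)
    counts = oc.outcome_table(fu, groups)
    for g, row in oc.REFERENCE_OUTCOME_COUNTS.items():
        for label, n in row.items():
            assert counts.loc[g, label] == n, (g, label)
    # column sums excluding missing: 68, 74, 11
    assert counts.loc["HC"].drop("missing").sum() == 68
    assert counts.loc["HC-like SMD"].drop("missing").sum() == 74
    assert counts.loc["AD-like SMD"].drop("missing").sum() == 11


def test_outcome_counts_conserve_group_sizes():
    fu, groups = oc.followup_from_counts(oc.REFERENCE_OUTCOME_COUNTS)
    counts = oc.outcome_table(fu, groups)
    sizes = pd.Series(groups).value_counts()
    for g in counts.index:
        assert counts.loc[g].sum() == sizes[g]


def test_outcome_table_requires_complete_group_map():
    fu, groups = oc.followup_from_counts({"HC": {"HC": 2}})
    del groups[next(iter(groups))]
    with pytest.raises(KeyError):
        oc.outcome_table(fu, groups)


def test_progression_proportions_and_ratio_match_printed_precision():
    fu, groups = oc.followup_from_counts(oc.REFERENCE_OUTCOME_COUNTS)
    counts = oc.outcome_table(fu, groups)
    s = oc.progression_stats(counts, "AD-like SMD", "HC")
    assert s["AD-like SMD"] == {"progressed": 8, "n": 11, "percent": 72.7}
    assert s["HC"] == {"progressed": 8, "n": 68, "percent": 11.8}
    assert s["ratio"] == 6.2
    s2 = oc.progression_stats(counts, "HC-like SMD", "HC")
    assert s2["HC-like SMD"]["percent"] == 17.6


def test_km_curve_matches_hand_computed_product_limit():
    """n=4: events at 18 and 54, censorings at 36 and 90.

    Hand table: t=18 risk 4, 1 event → 3/4; censor at 36 leaves risk
    {54, 90}; t=54 risk 2, 1 event → 3/4 · 1/2 = 3/8.
    """
    curve = oc.km_curve([(18, True), (36, False), (54, True), (90, False)])
    assert curve.survival_at(0) == pytest.approx(1.0)
    assert curve.survival_at(18) == pytest.approx(3 / 4)
    assert curve.survival_at(36) == pytest.approx(3 / 4)
    assert curve.survival_at(54) == pytest.approx(3 / 8)
    assert curve.survival_at(90) == pytest.approx(3 / 8)
    assert np.all(np.diff(curve.survival) <= 1e-12)  # non-increasing
    # degenerate variant: the last at-risk subject has the event
    tiny = oc.km_curve([(18, True), (36, False), (54, True)])
    assert tiny.survival_at(18) == pytest.approx(2 / 3)
    assert tiny.survival_at(54) == pytest.approx(0.0)


def test_km_no_events_stays_at_one():
    curve = oc.km_curve([(18, False), (54, False), (90, False)])
    assert np.allclose(curve.survival, 1.0)


def test_km_single_time_mass():
    curve = oc.km_curve([(36, True)] * 4)
    assert curve.survival_at(35.9) == 1.0
    assert curve.survival_at(36) == 0.0


def test_km_equals_one_minus_ecdf_without_censoring():
    rng = np.random.default_rng(8)
    times = rng.integers(1, 100, 25).astype(float)
    curve = oc.km_curve([(t, True) for t in times])
    for t in np.unique(times):
        assert curve.survival_at(t) == pytest.approx(np.mean(times > t))


def test_logrank_matches_hand_computed_oe_table():
    """Toy 6-subject example, all events, no ties across groups.

    Pooled event times 1..6 alternate groups A={1,3,5}, B={2,4,6}.
    Hand computation of O-E and hypergeometric variances:
      times: 1:(nA=3,nB=3,event A) E=.5 V=.25
             2:(2,3,B) E_A=.4 V=.24   3:(2,2,A) E=.5 V=.25
             4:(1,2,B) E_A=1/3 V=2/9  5:(1,1,A) E=.5 V=.25
             6:(0,1,B) E_A=0 V=0
      O_A=3, E_A=.5+.4+.5+1/3+.5=2.2333, V=1.2122
      chi2 = (3-2.2333)^2/1.2122 = 0.48497
    """
    a = [(1, True), (3, True), (5, True)]
    b = [(2, True), (4, True), (6, True)]
    res = oc.logrank(a, b)
    ea = 0.5 + 0.4 + 0.5 + 1 / 3 + 0.5
    v = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.25
    assert res["chi2"] == pytest.approx((3 - ea) ** 2 / v, rel=1e-6)
    assert res["df"] == 1
    assert 0 <= res["p"] <= 1


def test_logrank_identical_groups_give_zero():
    ev = [(18, True), (36, False), (54, True)]
    res = oc.logrank(ev, list(ev))
    assert res["chi2"] == pytest.approx(0.0, abs=1e-10)


def test_logrank_extreme_separation_is_significant():
    a = [(6, True)] * 10
    b = [(90, False)] * 10
    res = oc.logrank(a, b)
    assert res["chi2"] > 3.84 and res["p"] < 0.05


def test_logrank_requires_events():
    with pytest.raises(ValueError):
        oc.logrank([(10, False)], [(20, False)])


def test_mmse_dichotomization_boundary():
    assert oc.dichotomize_mmse([24, 23, 30, 0]) == \
        ["normal", "abnormal", "normal", "abnormal"]
    with pytest.raises(ValueError):
        oc.dichotomize_mmse([31])
    with pytest.raises(ValueError):
        oc.dichotomize_mmse([-1])


def test_pib_positivity_threshold():
    assert oc.classify_pib(1.5) == "positive"
    assert oc.classify_pib(1.49) == "negative"
    assert oc.classify_pib(3.0) == "positive"
    with pytest.raises(ValueError):
        oc.classify_pib(0.0)


def _bh_enumerate(p, q):
    """Direct step-up enumeration (oracle)."""
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    prev = 1.0
    for i in range(m, 0, -1):
        prev = min(prev, m / i * p[order[i - 1]])
        adj[order[i - 1]] = prev
    return adj, reject


def test_bh_worked_example():
    res = oc.bh_correct([0.01, 0.02, 0.04, 0.10], q=0.05)
    assert list(res["reject"]) == [True, True, False, False]


def test_bh_empty_and_uniform_inputs():
    assert oc.bh_correct([])["adjusted"].size == 0
    res = oc.bh_correct([0.001] * 14, q=0.05)
    assert res["reject"].all()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=12),
       st.floats(min_value=0.01, max_value=0.2))
def test_bh_matches_direct_enumeration(pvals, q):
    res = oc.bh_correct(pvals, q=q)
    adj, rej = _bh_enumerate(np.asarray(pvals), q)
    assert np.allclose(res["adjusted"], adj, atol=1e-12)
    assert np.array_equal(res["reject"], rej)


def test_bh_rejections_monotone_in_q():
    pvals = [0.003, 0.04, 0.021, 0.3, 0.0009, 0.11]
    prev = -1
    for q in (0.01, 0.05, 0.1, 0.2, 0.5):
        n = int(oc.bh_correct(pvals, q=q)["reject"].sum())
        assert n >= prev
        prev = n
    # single test: never rejects p > q
    assert not oc.bh_correct([0.06], q=0.05)["reject"][0]


def test_incidence_rate_ratio_toy():
    a = [(10, True), (10, True)]    # 2 events / 20 months
    b = [(50, True), (50, False)]   # 1 event / 100 months
    assert oc.incidence_rate_ratio(a, b) == pytest.approx(10.0)
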