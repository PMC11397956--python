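"""Beat matching, confusion rates, Bland–Altman, ICC and tables.

Expected values for the rate computations come from the published
per-stratum validation counts of a chest-strap/watch comparison study,
used here as fixed inputs; expected values for the matching logic come
from a brute-force optimal-assignment oracle built on
``scipy.optimize.linear_sum_assignment``.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from ecgval import (
    MatchResult,
    accuracy,
    bland_altman,
    confusion_summary,
    icc3_single,
    instantaneous_hr,
    match_peaks,
    paired_rr_differences,
    percent_of_mean,
    precision,
    rr_sd,
    sensitivity,
    specificity,
    stratified_report,
)

# published per-stratum counts: (activity, exercise, participants, TP, FN, FP)
CHEST_TABLE = [
    ("rest_pre", "running", 14, 4658, 23, 27),
    ("rest_pre", "cycling", 7, 2669, 3, 5),
    ("incremental", "running", 11, 40163, 175, 249),
    ("incremental", "cycling", 7, 23988, 33, 21),
    ("rest_post", "running", 12, 6463, 31, 30),
    ("rest_post", "cycling", 7, 3635, 17, 16),
]
WATCH_TABLE = [
    ("rest_pre", "running", 12, 3658, 176, 211),
    ("rest_pre", "cycling", 7, 2462, 214, 288),
    ("incremental", "running", 11, 31106, 6059, 4005),
    ("incremental", "cycling", 7, 18877, 4924, 4382),
    ("rest_post", "running", 12, 5592, 145, 57),
    ("rest_post", "cycling", 7, 3261, 116, 87),
]


def _rows(table):
    return [
        {"activity": a, "exercise": e, "participants": p, "tp": tp, "fn": fn, "fp": fp}
        for a, e, p, tp, fn, fp in table
    ]


def _optimal_tp(c, d, threshold):
    """Maximum-cardinality one-to-one pairing within the window (oracle)."""
    c, d = np.asarray(c, float), np.asarray(d, float)
    if c.size == 0 or d.size == 0:
        return 0
    cost = np.abs(c[:, None] - d[None, :])
    feasible = cost <= threshold
    cost = np.where(feasible, cost, 1e12)
    ri, ci = linear_sum_assignment(cost)
    return int(feasible[ri, ci].sum())


class TestMatchPeaks:
    def test_mixed_example(self):
        m = match_peaks([1000.0, 2000.0, 3000.0], [1040.0, 2950.0, 5000.0])
        assert (m.tp, m.fn, m.fp) == (2, 1, 1)
        assert _optimal_tp([1000, 2000, 3000], [1040, 2950, 5000], 100) == 2

    def test_identical_lists(self):
        t = 1e12 + 800.0 * np.arange(50)
        m = match_peaks(t, t)
        assert (m.tp, m.fn, m.fp) == (50, 0, 0)

    def test_boundary_is_inclusive(self):
        m = match_peaks([1000.0], [1100.0])
        assert m.tp == 1

    def test_empty_criterion(self):
        m = match_peaks([], [1000.0, 2000.0])
        assert (m.tp, m.fn, m.fp) == (0, 0, 2)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_greedy_matches_optimal_on_refractory_spaced_beats(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        c = np.cumsum(rng.uniform(250, 1200, rng.integers(2, 30)))
        keep = rng.random(c.size) > 0.2
        d = c[keep] + rng.uniform(-90, 90, int(keep.sum()))
        d.sort()
        if d.size > 1 and np.min(np.diff(d)) < 210:
            d = d[np.concatenate([[True], np.diff(d) >= 210])]
        m = match_peaks(c, d)
        assert m.tp == _optimal_tp(c, d, 100.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 5000))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.uniform(250, 1200, 20))
        b = np.cumsum(rng.uniform(250, 1200, 25))
        m_ab = match_peaks(a, b)
        m_ba = match_peaks(b, a)
        assert m_ab.tp == m_ba.tp
        assert (m_ab.fn, m_ab.fp) == (m_ba.fp, m_ba.fn)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 5000))
    def test_widening_threshold_never_loses_matches(self, seed):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.uniform(250, 1200, 30))
        b = a[rng.random(30) > 0.1] + rng.uniform(-150, 150, None)
        prev = 0
        for thr in (25.0, 50.0, 100.0, 150.0):
            tp = match_peaks(a, np.sort(b), threshold_ms=thr).tp
            assert tp >= prev
            prev = tp


class TestConfusionRates:
    def test_chest_sensor_printed_rates(self):
        m = MatchResult.from_counts(81576, 282, 348)
        s = confusion_summary(m, total_samples=81576 + 282 + 348 + 38_059_993)
        assert s.tn == 38_059_993
        assert round(s.specificity, 3) == 99.999
        assert round(s.accuracy, 3) == 99.998
        assert round(s.der, 3) == 0.002

    def test_watch_printed_rates(self):
        m = MatchResult.from_counts(64956, 11634, 9030)
        s = confusion_summary(m, total_samples=64956 + 11634 + 9030 + 37_454_530)
        assert round(s.accuracy, 3) == 99.945
        assert round(s.der, 3) == 0.055

    def test_perfect_detector(self):
        m = match_peaks([1000.0], [1000.0])
        s = confusion_summary(m, total_samples=1000)
        assert (s.specificity, s.accuracy, s.der) == (100.0, 100.0, 0.0)

    def test_undefined_rates_are_nan_not_zero(self):
        assert math.isnan(sensitivity(0, 0))
        assert math.isnan(precision(0, 0))

    @pytest.mark.parametrize(
        "fn,args,expected",
        [
            (sensitivity, (4658, 23), 99.51),
            (sensitivity, (3658, 176), 95.41),
            (sensitivity, (10, 0), 100.0),
            (precision, (3658, 211), 94.55),
            (precision, (23988, 21), 99.91),
            (precision, (10, 0), 100.0),
        ],
    )
    def test_published_row_rates(self, fn, args, expected):
        assert round(fn(*args), 2) == expected


class TestPairedRRDifferences:
    def test_identical_streams_give_zero_diffs(self):
        t = 1e12 + 800.0 * np.arange(30)
        d = paired_rr_differences(match_peaks(t, t))
        assert len(d) == 29
        assert np.all(d["diff_ms"] == 0)

    def test_constant_shift_cancels_in_intervals(self):
        t = 1e12 + 800.0 * np.arange(30)
        d = paired_rr_differences(match_peaks(t, t + 10.0))
        assert np.allclose(d["diff_ms"], 0.0)

    def test_intervals_spanning_a_missed_beat_are_excluded(self):
        t = 1e12 + 800.0 * np.arange(10)
        device = np.delete(t, 5)
        d = paired_rr_differences(match_peaks(t, device))
        # 9 criterion intervals; the two touching the missed beat drop out
        assert len(d) == 7
        assert np.all(np.abs(d["diff_ms"]) < 1e-9)  # never compared to a doubled interval


class TestBlandAltman:
    def test_all_zero(self):
        rep = bland_altman([0.0, 0.0, 0.0])
        assert rep.mean_diff_ms == 0.0 and rep.sd_diff_ms == 0.0

    def test_two_point_closed_form(self):
        rep = bland_altman([-1.0, 1.0])
        assert rep.mean_diff_ms == 0.0
        assert rep.sd_diff_ms == pytest.approx(math.sqrt(2), abs=1e-12)
        assert rep.loa_high_ms == pytest.approx(1.96 * math.sqrt(2))

    def test_single_value_is_an_error(self):
        with pytest.raises(ValueError):
            bland_altman([1.0])


class TestScalarStats:
    @pytest.mark.parametrize("rr,bpm", [(1000.0, 60.0), (390.3, 153.7), (400.5, 149.8)])
    def test_instantaneous_hr(self, rr, bpm):
        assert round(instantaneous_hr(rr), 1) == bpm

    def test_instantaneous_hr_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            instantaneous_hr(0.0)

    def test_icc3_identical_columns(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc3_single(m) == pytest.approx(1.0)

    def test_icc3_ignores_fixed_offset(self):
        a = np.array([3.0, 9.0, 1.0, 7.0, 5.0])
        assert icc3_single(np.column_stack([a, a + 42.0])) == pytest.approx(1.0)

    def test_icc3_toy_matrix_against_anova_oracle(self):
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0], [4.0, 6.0]])
        # independent mean-squares computation, spelled out
        n, k = m.shape
        grand = m.sum() / (n * k)
        ms_rows = k * sum((row.mean() - grand) ** 2 for row in m) / (n - 1)
        ss_cols = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k))
        ss_err = ((m - grand) ** 2).sum() - (n - 1) * ms_rows - ss_cols
        ms_err = ss_err / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        assert icc3_single(m) == pytest.approx(expected, abs=1e-10)

    def test_icc3_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        a = rng.normal(100, 20, 15)
        m = np.column_stack([a, a + rng.normal(0, 5, 15)])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "score": m.flatten(),
            }
        )
        tab = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = float(tab.loc[tab["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc3_single(m) == pytest.approx(ref, abs=1e-9)

    def test_icc3_zero_between_subject_variance_is_nan(self):
        assert math.isnan(icc3_single(np.ones((4, 2))))

    @pytest.mark.parametrize(
        "rr,expected", [([800.0, 800.0, 800.0], 0.0), ([700.0, 900.0], 141.42)]
    )
    def test_rr_sd_closed_forms(self, rr, expected):
        assert round(rr_sd(rr), 2) == expected

    def test_rr_sd_recovers_generator_sdnn(self):
        rng = np.random.default_rng(8)
        rr = rng.normal(900.0, 95.0, 300)
        assert rr_sd(rr) == pytest.approx(95.0, rel=0.10)

    @pytest.mark.parametrize(
        "diff,ref,expected", [(0.38, 400.5, 0.09), (-22.7, 95.54, -23.76), (0.0, 5.0, 0.0)]
    )
    def test_percent_of_mean(self, diff, ref, expected):
        assert round(percent_of_mean(diff, ref), 2) == expected

    def test_percent_of_mean_zero_reference(self):
        with pytest.raises(ValueError):
            percent_of_mean(1.0, 0.0)


class TestStratifiedReport:
    def test_chest_table_pools_to_published_overall(self):
        out = stratified_report(_rows(CHEST_TABLE))
        overall = out[out["activity"] == "Overall"].iloc[0]
        assert round(overall["sensitivity"], 2) == 99.66
        assert round(overall["precision"], 2) == 99.58

    def test_watch_table_pools_to_published_overall(self):
        out = stratified_report(_rows(WATCH_TABLE))
        overall = out[out["activity"] == "Overall"].iloc[0]
        assert round(overall["sensitivity"], 2) == 84.81
        assert round(overall["precision"], 2) == 87.79

    def test_watch_resting_strata_pool(self):
        rest = [r for r in _rows(WATCH_TABLE) if r["activity"] != "incremental"]
        overall = stratified_report(rest)
        overall = overall[overall["activity"] == "Overall"].iloc[0]
        assert round(overall["sensitivity"], 2) == 95.83
        assert round(overall["precision"], 2) == 95.88

    def test_single_stratum_pool_equals_stratum(self):
        out = stratified_report(_rows(CHEST_TABLE)[:1])
        assert out.iloc[0]["sensitivity"] == out.iloc[-1]["sensitivity"]

    def test_pooled_rate_bounded_by_strata(self):
        out = stratified_report(_rows(WATCH_TABLE))
        strata = out[out["activity"] != "Overall"]
        overall = out[out["activity"] == "Overall"].iloc[0]
        assert strata["sensitivity"].min() <= overall["sensitivity"] <= strata["sensitivity"].max()
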