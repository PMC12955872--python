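"""Cohort statistics: window summaries, event rates, reduction arithmetic,
treatment-window breakpoints and variance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbfus.analysis import (event_histogram, relative_event_reduction,
                            session_metrics, treatment_window, variance_tests)
from mbfus.control import ControllerConfig, Protocol, TreatmentSession


def make_session(l7, broadband=None, phase="controlling", predictions=None):
    n = len(l7)
    broadband = np.zeros(n) if broadband is None else np.asarray(broadband)
    df = pd.DataFrame({
        "time": np.arange(n, dtype=float), "h7": l7,
        "broadband_db": broadband, "event": broadband > 6.0,
        "prediction": predictions if predictions is not None else [False] * n,
        "phase": [phase] * n, "pressure_mpa": 0.2,
    })
    return TreatmentSession(records=df, config=ControllerConfig(mode="cl"),
                            protocol=Protocol(), seed=0, cumulative_dose=1.0)


class TestSessionMetrics:
    def test_constant_level_zero_sd_undefined_skew(self):
        m = session_metrics(make_session(np.full(30, 30.0)))
        assert m.mean_l7_db == 30.0 and m.sd_l7_db == 0.0
        assert m.skewness == 0.0 and not m.skewness_defined

    def test_symmetric_sample_zero_skew(self):
        l7 = np.tile([28.0, 32.0], 10)
        m = session_metrics(make_session(l7))
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(1)
        l7 = rng.normal(30, 2, size=20)
        m = session_metrics(make_session(l7))
        assert m.mean_l7_db == pytest.approx(l7.mean(), abs=1e-12)
        assert m.sd_l7_db == pytest.approx(l7.std(ddof=1), abs=1e-12)
        assert m.skewness == pytest.approx(stats.skew(l7, bias=False), abs=1e-12)

    def test_window_restricted_to_20s_after_arrival(self):
        n = 60
        df_l7 = np.concatenate([np.zeros(10), np.full(50, 30.0)])
        phases = ["waiting"] * 10 + ["controlling"] * 50
        df = pd.DataFrame({
            "time": np.arange(n, dtype=float), "h7": df_l7,
            "broadband_db": 0.0, "event": False, "prediction": False,
            "phase": phases, "pressure_mpa": 0.2})
        sess = TreatmentSession(records=df, config=ControllerConfig(mode="cl"),
                                protocol=Protocol(), seed=0, cumulative_dose=0.0)
        m = session_metrics(sess, window_s=20.0)
        assert m.mean_l7_db == 30.0  # only post-arrival pulses counted

    def test_never_activated_rejected(self):
        with pytest.raises(ValueError):
            session_metrics(make_session(np.zeros(10), phase="waiting"))


class TestEventHistogram:
    def test_no_events_zero_rate(self):
        out = event_histogram([make_session(np.zeros(50))])
        assert out["events"] == 0 and out["event_rate"] == 0.0

    def test_constructed_14_in_1048(self):
        bb = np.zeros(1048)
        bb[:14] = 8.0  # 14 events
        sessions = [make_session(np.zeros(524), bb[:524]),
                    make_session(np.zeros(524), bb[524:])]
        out = event_histogram(sessions)
        assert out["events"] == 14 and out["total_pulses"] == 1048
        assert out["event_rate"] == pytest.approx(14 / 1048)

    def test_rates_additive_and_order_invariant(self):
        a = make_session(np.zeros(100), np.r_[np.full(5, 9.0), np.zeros(95)])
        b = make_session(np.zeros(300), np.r_[np.full(3, 9.0), np.zeros(297)])
        r_ab = event_histogram([a, b])
        r_ba = event_histogram([b, a])
        assert r_ab["events"] == r_ba["events"] == 8
        assert r_ab["event_rate"] == pytest.approx(8 / 400)


class TestRelativeEventReduction:
    def test_paper_style_14_vs_1(self):
        red = relative_event_reduction(14 / 1048, 1 / 1048)
        assert round(red) == 93

    def test_equal_rates_zero_and_zero_rate_b_hundred(self):
        assert relative_event_reduction(0.5, 0.5) == 0.0
        assert relative_event_reduction(0.5, 0.0) == 100.0

    def test_zero_reference_rejected_and_monotone(self):
        with pytest.raises(ValueError):
            relative_event_reduction(0.0, 0.1)
        grid = [relative_event_reduction(0.2, rb) for rb in np.linspace(0, 0.2, 9)]
        assert all(x > y for x, y in zip(grid, grid[1:]))


class TestTreatmentWindow:
    def test_known_breakpoint_recovered(self):
        p = np.arange(0.10, 0.41, 0.02)
        bb = np.where(p <= 0.26, 1.0, 1.0 + 50 * (p - 0.26))  # kink at 0.26
        proxy = np.where(p >= 0.14, 5.0, 0.0)
        bg = np.array([0.0, 0.1, -0.1, 0.05])
        w = treatment_window(p, proxy, bb, bg)
        assert w.upper_bound == pytest.approx(0.26, abs=0.02 + 1e-9)
        assert w.lower_bound == pytest.approx(0.14, abs=1e-9)
        assert w.width > 0 and not w.empty

    def test_breakpoint_robust_to_mild_noise(self):
        rng = np.random.default_rng(3)
        p = np.arange(0.10, 0.41, 0.02)
        bb = np.where(p <= 0.26, 1.0, 1.0 + 60 * (p - 0.26)) + rng.normal(0, 1.0, p.size)
        proxy = np.where(p >= 0.14, 5.0, 0.0)
        w = treatment_window(p, proxy, bb, np.zeros(5))
        assert abs(w.upper_bound - 0.26) <= 0.04 + 1e-9  # within 2 grid steps

    def test_flat_broadband_open_ended(self):
        p = np.linspace(0.1, 0.4, 10)
        w = treatment_window(p, np.full(10, 5.0), np.ones(10), np.zeros(4))
        assert w.open_ended and w.upper_bound is None

    def test_no_proxy_rise_empty_window(self):
        p = np.linspace(0.1, 0.4, 10)
        w = treatment_window(p, np.zeros(10), np.ones(10), np.full(4, 1.0))
        assert w.empty and w.lower_bound is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            treatment_window(np.ones(5), np.ones(5), np.ones(5), np.ones(3))


class TestVarianceTests:
    def test_identical_groups_unit_f(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = variance_tests(g, g)
        assert out["f_statistic"] == pytest.approx(1.0)

    def test_doubled_deviations_give_f_of_four(self):
        a = np.array([-1.0, 0.0, 1.0, -1.0, 1.0])
        out = variance_tests(a, 2 * a)
        assert out["f_statistic"] == pytest.approx(4.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 2, 12)
        out = variance_tests(a, b)
        f = b.var(ddof=1) / a.var(ddof=1)
        assert out["f_statistic"] == pytest.approx(f, abs=1e-12)
        cdf = stats.f.cdf(f, 11, 14)
        assert out["f_pvalue"] == pytest.approx(2 * min(cdf, 1 - cdf), abs=1e-12)
        lev = stats.levene(a, b)
        assert out["levene_statistic"] == pytest.approx(lev.statistic)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            variance_tests(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            variance_tests(np.ones(2), np.ones(5))
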