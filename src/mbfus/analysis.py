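"""Session- and cohort-level statistics for controlled sonications.

Covers the quantities used to compare controllers: 7th-harmonic summaries
over the post-arrival window, broadband event histograms and rates, relative
event reduction between controllers, the acoustic treatment window (pressure
interval between opening onset and broadband inflection), and variance-
comparison tests (F and Levene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .control import TreatmentSession

__all__ = [
    "SessionMetrics",
    "TreatmentWindow",
    "session_metrics",
    "event_histogram",
    "relative_event_reduction",
    "treatment_window",
    "variance_tests",
]


@dataclass
class SessionMetrics:
    mean_l7_db: float
    sd_l7_db: float
    skewness: float
    skewness_defined: bool
    event_count: int
    prediction_count: int
    total_pulses: int
    dose_proxy: float

    @property
    def event_rate(self) -> float:
        return self.event_count / self.total_pulses

    @property
    def prediction_rate(self) -> float:
        return self.prediction_count / self.total_pulses


@dataclass
class TreatmentWindow:
    lower_bound: float | None   # MPa; opening-proxy rise above background
    upper_bound: float | None   # MPa; broadband inflection (breakpoint)
    empty: bool = False
    open_ended: bool = False

    @property
    def width(self) -> float | None:
        if self.lower_bound is None or self.upper_bound is None:
            return None
        return self.upper_bound - self.lower_bound


def session_metrics(session: TreatmentSession, window_s: float = 20.0) -> SessionMetrics:
    """Statistics over the ``window_s`` seconds following microbubble arrival.

    Arrival is the first pulse past the waiting phase.  SD is the sample
    standard deviation (n-1); skewness is the adjusted Fisher-Pearson
    coefficient, reported as 0 with ``skewness_defined=False`` for degenerate
    (zero-variance) windows.
    """
    rec = session.records
    active = rec[rec["phase"] != "waiting"]
    if active.empty:
        raise ValueError("session has no microbubble-arrival marker (never activated)")
    start = active["time"].iloc[0]
    win = rec[(rec["time"] >= start) & (rec["time"] < start + window_s)]
    if len(win) < 3:
        raise ValueError("analysis window contains fewer than 3 pulses")
    l7 = win["h7"].to_numpy(dtype=float)
    sd = float(np.std(l7, ddof=1))
    if sd == 0:
        skew, defined = 0.0, False
    else:
        skew = float(stats.skew(l7, bias=False))
        defined = bool(np.isfinite(skew))
        if not defined:
            skew = 0.0
    return SessionMetrics(
        mean_l7_db=float(np.mean(l7)), sd_l7_db=sd,
        skewness=skew, skewness_defined=defined,
        event_count=int(rec["event"].sum()),
        prediction_count=int(rec["prediction"].sum()) if "prediction" in rec else 0,
        total_pulses=len(rec), dose_proxy=session.cumulative_dose)


def event_histogram(sessions: list[TreatmentSession],
                    bins: np.ndarray | None = None,
                    event_threshold_db: float = 6.0) -> dict:
    """Pooled broadband-level histogram and event rate over sessions.

    The rate is ``events / total pulses`` with the strict >threshold rule, so
    it is invariant under session re-ordering and additive over
    concatenation.
    """
    if not sessions:
        raise ValueError("need at least one session")
    levels = np.concatenate([s.records["broadband_db"].to_numpy() for s in sessions])
    if bins is None:
        bins = np.arange(np.floor(levels.min()), np.ceil(levels.max()) + 1.0, 1.0)
    counts, edges = np.histogram(levels, bins=bins)
    events = int(np.sum(levels > event_threshold_db))
    return {
        "counts": counts, "bin_edges": edges,
        "events": events, "total_pulses": int(levels.size),
        "event_rate": events / levels.size,
    }


def relative_event_reduction(rate_a: float, rate_b: float) -> float:
    """Percent reduction of ``rate_b`` relative to ``rate_a``:
    ``(1 - rate_b / rate_a) * 100``."""
    if rate_a <= 0:
        raise ValueError("reference rate must be positive")
    return (1.0 - rate_b / rate_a) * 100.0


def _two_segment_breakpoint(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-segment piecewise-linear fit; returns (breakpoint, sse).

    Candidate breakpoints are the interior grid points; each candidate splits
    the data into two independently fitted line segments and the candidate
    minimizing the total SSE wins (first minimum on ties).
    """
    best_bp, best_sse = None, np.inf
    for i in range(2, len(x) - 1):
        sse = 0.0
        for seg in (slice(0, i + 1), slice(i, len(x))):
            xs, ys = x[seg], y[seg]
            coef = np.polyfit(xs, ys, 1)
            sse += float(np.sum((np.polyval(coef, xs) - ys) ** 2))
        if sse < best_sse - 1e-15:
            best_sse, best_bp = sse, float(x[i])
    return best_bp, best_sse


def treatment_window(pressure_grid: np.ndarray, opening_proxy: np.ndarray,
                     broadband_levels: np.ndarray,
                     background_proxy: np.ndarray) -> TreatmentWindow:
    """Acoustic treatment window from a pressure sweep.

    Lower bound: the smallest pressure whose opening proxy exceeds the
    background mean + 2 SD.  Upper bound: the breakpoint of a two-segment
    piecewise-linear least-squares fit to broadband level vs pressure (the
    inflection where broadband emission starts to grow); flagged open-ended
    when the fit shows no meaningful slope change (flat response).
    """
    p = np.asarray(pressure_grid, dtype=float)
    if p.size < 6:
        raise ValueError("need at least 6 pressure points")
    proxy = np.asarray(opening_proxy, dtype=float)
    bb = np.asarray(broadband_levels, dtype=float)
    bg = np.asarray(background_proxy, dtype=float)
    if proxy.shape != p.shape or bb.shape != p.shape:
        raise ValueError("grids must be aligned")

    cutoff = bg.mean() + 2.0 * bg.std(ddof=1) if bg.size > 1 else bg.mean()
    above = np.nonzero(proxy > cutoff)[0]
    if above.size == 0:
        return TreatmentWindow(lower_bound=None, upper_bound=None, empty=True)
    lower = float(p[above[0]])

    bp, sse = _two_segment_breakpoint(p, bb)
    # flat response: a single line explains the data essentially as well
    coef = np.polyfit(p, bb, 1)
    sse1 = float(np.sum((np.polyval(coef, p) - bb) ** 2))
    spread = float(np.sum((bb - bb.mean()) ** 2))
    if spread < 1e-12 or (sse1 - sse) < 0.01 * max(spread, 1e-12):
        return TreatmentWindow(lower_bound=lower, upper_bound=None, open_ended=True)
    if bp is not None and bp < lower:
        return TreatmentWindow(lower_bound=lower, upper_bound=bp, empty=True)
    return TreatmentWindow(lower_bound=lower, upper_bound=bp)


def variance_tests(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Variance comparison: the classical F-test (ratio of sample variances,
    two-sided) and Levene's test (robust to non-normality)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    f_stat = vb / va if va > 0 else np.inf
    dfa, dfb = a.size - 1, b.size - 1
    if np.isfinite(f_stat):
        cdf = stats.f.cdf(f_stat, dfb, dfa)
        f_p = 2.0 * min(cdf, 1.0 - cdf)
    else:
        f_p = 0.0
    lev_stat, lev_p = stats.levene(a, b)
    return {
        "f_statistic": float(f_stat), "f_pvalue": float(min(f_p, 1.0)),
        "levene_statistic": float(lev_stat), "levene_pvalue": float(lev_p),
    }
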