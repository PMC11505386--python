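"""Outcome metrics for EGCO2 regulation traces.

Definitions follow the benchtop convention:

* *Settling time* after a metabolic change: the time from when EGCO2 first
  diverges from the target by more than 5 mmHg until it re-enters the
  +-5 mmHg band and stays there for at least 3 s.  The settling interval
  ends at band entry; the 3 s sustain is a qualification, not part of the
  duration.  A trace that never diverges settles in 0 min; one that never
  re-enters is reported as not settled (``None``), never as a large number.
* *Overshoot / undershoot*: the largest absolute EGCO2 excursion from the
  target within a transition window.
* *Segment statistics*: mean/SD/max/min of EGCO2 per schedule segment,
  excluding the first 120 s after each change so the numbers describe the
  steady state; whole-run statistics include the transition periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BAND_MMHG = 5.0
SUSTAIN_S = 3.0
STEADY_EXCLUDE_S = 120.0


def _as_arrays(trace, column: str = "egco2_sensed_mmHg"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Accept a trace DataFrame or (times, values) pair."""
    if isinstance(trace, pd.DataFrame):
        return trace["time_s"].to_numpy(float), trace[column].to_numpy(float)
    t, v = trace
    return np.asarray(t, float), np.asarray(v, float)


def sustained_band_entry(t: np.ndarray, err: np.ndarray, start_idx: int,
                         band: float = BAND_MMHG,
                         sustain: float = SUSTAIN_S) -> int | None:
    """Index of the first entry into ``|err| <= band`` held for ``sustain`` s.

    The sustain window must be fully covered by the trace; entries too
    close to the end of the trace do not qualify.
    """
    inside = np.abs(err) <= band
    n = len(t)
    i = start_idx
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        verdict: bool | None = None
        while j < n:
            if not inside[j]:
                verdict = False
                break
            if t[j] - t[i] >= sustain - 1e-9:
                verdict = True
                break
            j += 1
        if verdict:
            return i
        if verdict is False:
            # Any candidate between i and j also has the exit inside its
            # sustain window; skip past the band exit.
            i = j + 1
        else:
            return None   # trace ended before the sustain window elapsed
    return None


def settling_time(trace, target: float, change_time: float,
                  end_time: float | None = None,
                  column: str = "egco2_sensed_mmHg",
                  band: float = BAND_MMHG,
                  sustain: float = SUSTAIN_S) -> float | None:
    """Settling time in minutes after the metabolic change at ``change_time``.

    Returns 0.0 if EGCO2 never leaves the +-band after the change, ``None``
    (not settled) if it diverges but never re-enters sustainably.
    """
    t, v = _as_arrays(trace, column)
    if len(t) == 0 or change_time < t[0] - 1e-9 or change_time > t[-1] + 1e-9:
        raise ValueError("change_time outside trace")
    mask = t >= change_time - 1e-9
    if end_time is not None:
        mask &= t <= end_time + 1e-9
    tt, vv = t[mask], v[mask]
    err = vv - target
    out = np.nonzero(np.abs(err) > band)[0]
    if len(out) == 0:
        return 0.0
    diverge = out[0]
    entry = sustained_band_entry(tt, err, diverge, band, sustain)
    if entry is None:
        return None
    return (tt[entry] - tt[diverge]) / 60.0


def overshoot(trace, target: float, window: tuple[float, float],
              column: str = "egco2_sensed_mmHg") -> float:
    """Max |EGCO2 - target| (mmHg) within the transition ``window``."""
    t, v = _as_arrays(trace, column)
    lo, hi = window
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError("empty transition window")
    return float(np.max(np.abs(v[mask] - target)))


@dataclass
class SegmentStats:
    start_s: float
    end_s: float
    mean: float
    sd: float
    max: float
    min: float
    n: int


@dataclass
class MetricsReport:
    """Settling / overshoot per transition plus segment and run statistics."""

    target: float | None
    settling_min: list[float | None] = field(default_factory=list)
    overshoot_mmHg: list[float] = field(default_factory=list)
    segments: list[SegmentStats] = field(default_factory=list)
    whole_run: SegmentStats | None = None
    band_violation_fraction: float | None = None

    def frame(self) -> pd.DataFrame:
        rows = [{"segment_start_s": s.start_s, "segment_end_s": s.end_s,
                 "mean_mmHg": s.mean, "sd_mmHg": s.sd, "max_mmHg": s.max,
                 "min_mmHg": s.min, "n": s.n} for s in self.segments]
        return pd.DataFrame(rows)


def _stats(t: np.ndarray, v: np.ndarray, lo: float, hi: float
           ) -> SegmentStats | None:
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not mask.any():
        return None
    vv = v[mask]
    return SegmentStats(start_s=lo, end_s=hi, mean=float(vv.mean()),
                        sd=float(vv.std(ddof=0)), max=float(vv.max()),
                        min=float(vv.min()), n=int(mask.sum()))


def segment_stats(trace, change_times: list[float],
                  target: float | None = None,
                  column: str = "egco2_sensed_mmHg",
                  exclude_s: float = STEADY_EXCLUDE_S) -> MetricsReport:
    """Per-segment steady-state statistics plus whole-run statistics.

    Segments run between consecutive change times (plus trace start/end);
    the first ``exclude_s`` seconds after each change are dropped from the
    per-segment numbers.  Segments shorter than ``exclude_s`` are skipped.
    Whole-run statistics include everything, transitions and all.
    """
    t, v = _as_arrays(trace, column)
    edges = [t[0]] + [c for c in change_times if t[0] < c < t[-1]] + [t[-1]]
    report = MetricsReport(target=target)
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo <= exclude_s:
            continue    # too short to contain a steady-state window
        s = _stats(t, v, lo + exclude_s, hi)
        if s is not None:
            report.segments.append(s)
    report.whole_run = _stats(t, v, t[0], t[-1] + 1.0)
    if target is not None:
        for c in change_times:
            nxt = min([e for e in edges if e > c], default=t[-1])
            st = settling_time((t, v), target, c, end_time=nxt)
            report.settling_min.append(st)
            if st is not None:
                end = c + st * 60.0 if st > 0 else nxt
            else:
                end = nxt
            report.overshoot_mmHg.append(
                overshoot((t, v), target, (c, max(end, c + 1.0))))
        steady = np.zeros_like(t, dtype=bool)
        for lo, hi in zip(edges[:-1], edges[1:]):
            steady |= (t >= lo + exclude_s) & (t < hi)
        if steady.any():
            report.band_violation_fraction = float(
                np.mean(np.abs(v[steady] - target) > BAND_MMHG))
    return report


def compare_runs(on_trace, off_traces: dict[str, object],
                 change_times: list[float], target: float,
                 column: str = "egco2_sensed_mmHg") -> pd.DataFrame:
    """Controller-on vs fixed-sweep comparison (whole-run EGCO2 statistics).

    All traces must share the same schedule; rows carry avg/SD/max/min over
    the entire run (transitions included) and the on/off SD ratio.
    """
    def _whole(trace) -> SegmentStats:
        t, v = _as_arrays(trace, column)
        return _stats(t, v, t[0], t[-1] + 1.0)

    def _duration(trace) -> float:
        t, _ = _as_arrays(trace, column)
        return float(t[-1] - t[0])

    d_on = _duration(on_trace)
    for name, tr in off_traces.items():
        if abs(_duration(tr) - d_on) > 1.0:
            raise ValueError(f"trace {name!r} does not match the "
                             "controller-on schedule")
    on = _whole(on_trace)
    rows = [{"arm": "controller_on", "target_mmHg": target,
             "avg_mmHg": on.mean, "sd_mmHg": on.sd, "max_mmHg": on.max,
             "min_mmHg": on.min, "sd_ratio_vs_on": 1.0}]
    for name, tr in off_traces.items():
        s = _whole(tr)
        rows.append({"arm": name, "target_mmHg": target, "avg_mmHg": s.mean,
                     "sd_mmHg": s.sd, "max_mmHg": s.max, "min_mmHg": s.min,
                     "sd_ratio_vs_on": s.sd / on.sd if on.sd > 0
                     else math.inf})
    return pd.DataFrame(rows)


def settling_time_bruteforce(t: np.ndarray, v: np.ndarray, target: float,
                             change_time: float,
                             band: float = BAND_MMHG,
                             sustain: float = SUSTAIN_S) -> float | None:
    """Independent O(n^2) scan oracle for :func:`settling_time`.

    Checks every sample after the divergence as a candidate band entry and
    verifies the sustain window exhaustively.  Used in tests only.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    sel = t >= change_time - 1e-9
    tt, vv = t[sel], v[sel]
    err = np.abs(vv - target)
    div = None
    for i in range(len(tt)):
        if err[i] > band:
            div = i
            break
    if div is None:
        return 0.0
    for i in range(div, len(tt)):
        if err[i] > band:
            continue
        qualified = False
        for j in range(i, len(tt)):
            if err[j] > band:
                break
            if tt[j] - tt[i] >= sustain - 1e-9:
                qualified = True
                break
        if qualified:
            return (tt[i] - tt[div]) / 60.0
    return None
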