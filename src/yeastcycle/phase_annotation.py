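"""Cell cycle phase detection from simulated trajectories.

Transition markers (all thresholds relative, taken per cycle so runs with
different amplitudes annotate identically):

* START — onset of SBF-dependent transcription together with nuclear
  exclusion of Whi5: earliest time at which free SBF exceeds half its
  per-cycle maximum while nuclear Whi5 (Whi5 + SBF_Whi5) is below half of
  its per-cycle maximum;
* G1/S — upward crossing of Clb5_total through half of its per-cycle
  maximum;
* G2/M — upward crossing of Clb2_total through half of its per-cycle
  maximum;
* M exit — downward crossing of *active* (free, unphosphorylated) Clb2
  through half of its per-cycle maximum after the G2/M peak.  The M→G1
  boundary has no canonical marker; the falling edge of Clb2 kinase
  activity captures APC/Cdc14/Sic1-driven Clb2 destruction as well as
  Swe1-mediated inactivation (the route by which osmotic stress in M
  drives early mitotic exit), and is documented as a package convention.

Cycles are delimited by successive minima of Clb2_total; crossing times are
linearly interpolated between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .perturbation import SignalSchedule
from .simulation import Trajectory

__all__ = ["CycleRecord", "PhaseAnnotation", "detect_transitions",
           "classify_arrest", "ArrestReport"]

PHASE_G1 = "G1"
PHASE_SG2 = "S/G2"
PHASE_M = "M"

_MIN_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class CycleRecord:
    """Event times (minutes) of one detected cycle."""

    index: int
    window: tuple[float, float]
    start_time: float | None
    g1s_time: float | None
    g2m_time: float | None
    mexit_time: float | None

    @property
    def complete(self) -> bool:
        times = (self.start_time, self.g1s_time, self.g2m_time, self.mexit_time)
        if any(t is None for t in times):
            return False
        return times[0] < times[1] < times[2] < times[3]


@dataclass(frozen=True)
class PhaseAnnotation:
    cycles: tuple[CycleRecord, ...]
    labels: np.ndarray  # per-grid-point phase label (object dtype)
    times: np.ndarray

    @property
    def complete_cycles(self) -> tuple[CycleRecord, ...]:
        return tuple(c for c in self.cycles if c.complete)

    def event_times(self, event: str) -> np.ndarray:
        attr = {"start": "start_time", "g1s": "g1s_time",
                "g2m": "g2m_time", "mexit": "mexit_time"}[event]
        return np.array([getattr(c, attr) for c in self.cycles
                         if getattr(c, attr) is not None])

    def frame(self) -> pd.DataFrame:
        """Long-form event table (cycle index, event, time in minutes)."""
        rows = []
        for c in self.cycles:
            for event, t in (("START", c.start_time), ("G1/S", c.g1s_time),
                             ("G2/M", c.g2m_time), ("M-exit", c.mexit_time)):
                if t is not None:
                    rows.append({"cycle": c.index, "event": event, "time": t})
        return pd.DataFrame(rows, columns=["cycle", "event", "time"])

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format="%.10g")


def _cross_up(t, x, threshold, t_lo, t_hi):
    """First interpolated upward crossing of ``threshold`` in [t_lo, t_hi]."""
    mask = (t >= t_lo) & (t <= t_hi)
    idx = np.nonzero(mask)[0]
    for i, j in zip(idx[:-1], idx[1:]):
        if x[i] < threshold <= x[j]:
            f = (threshold - x[i]) / (x[j] - x[i])
            return float(t[i] + f * (t[j] - t[i]))
    return None


def _cross_down(t, x, threshold, t_lo, t_hi):
    mask = (t >= t_lo) & (t <= t_hi)
    idx = np.nonzero(mask)[0]
    for i, j in zip(idx[:-1], idx[1:]):
        if x[i] >= threshold > x[j]:
            f = (x[i] - threshold) / (x[i] - x[j])
            return float(t[i] + f * (t[j] - t[i]))
    return None


def _find_start(t, sbf, whi5, t_lo, t_hi):
    """Commitment time: SBF above half-max and nuclear Whi5 below half-max.

    START is the point of no return, so the marker pair must hold
    continuously through to the end of the search window (S entry): a
    transient partial Whi5 exclusion that re-binds SBF (e.g. under a
    pheromone brake engaging just before commitment) does not count.
    The returned time is the onset of the final contiguous stretch on
    which both conditions hold.
    """
    sub = np.nonzero((t >= t_lo) & (t <= t_hi))[0]
    if sub.size == 0:
        return None
    half_sbf = 0.5 * sbf[sub].max()
    half_whi5 = 0.5 * whi5[sub].max()
    both = (sbf[sub] > half_sbf) & (whi5[sub] < half_whi5)
    if not both[-1]:
        return None
    false_idx = np.nonzero(~both)[0]
    first_of_final_run = false_idx[-1] + 1 if false_idx.size else 0
    j = sub[first_of_final_run]
    if j > 0:
        # refine with the later of the two interpolated single-marker
        # crossings entering this grid interval
        up = _cross_up(t, sbf, half_sbf, t[j - 1], t[j])
        down = _cross_down(t, whi5, half_whi5, t[j - 1], t[j])
        candidates = [c for c in (up, down) if c is not None]
        return max(candidates) if candidates else float(t[j])
    return float(t[j])


def detect_transitions(trajectory: Trajectory) -> PhaseAnnotation:
    """Annotate START, G1/S, G2/M and M-exit events along a trajectory.

    Cycles are anchored on successive Clb2_total peaks: the events leading
    into mitosis (START, G1/S, G2/M) are located between the previous peak
    and the anchoring peak, M exit just after it.  A trailing partial record
    captures events of an unfinished (e.g. arrested) final cycle.
    """
    t = trajectory.times
    clb2 = trajectory.column("Clb2_total")
    clb2a = trajectory.column("Clb2_active")
    clb5 = trajectory.column("Clb5_total")
    whi5 = trajectory.column("Whi5_nuclear")
    sbf = trajectory.column("SBF_active")

    rng = clb2.max() - clb2.min()
    scale = max(abs(float(clb2.max())), 1e-12)
    if rng < 1e-3 * scale:
        return PhaseAnnotation(cycles=(), labels=_label_grid(t, ()), times=t)
    peaks, _ = find_peaks(clb2, prominence=_MIN_PROMINENCE_FRACTION * rng)
    if peaks.size == 0:
        return PhaseAnnotation(cycles=(), labels=_label_grid(t, ()), times=t)

    peak_times = t[peaks]
    cycles = []
    for k, tp in enumerate(peak_times):
        w_lo = float(peak_times[k - 1]) if k > 0 else float(t[0])
        w_hi = float(peak_times[k + 1]) if k + 1 < peak_times.size else float(t[-1])
        span = (t >= w_lo) & (t <= tp)
        half_clb2 = 0.5 * clb2[span].max()
        g2m = _cross_up(t, clb2, half_clb2, w_lo, tp)
        act_span = (t >= w_lo) & (t <= w_hi)
        half_act = 0.5 * clb2a[act_span].max()
        mexit = _cross_down(t, clb2a, half_act, tp, w_hi)
        half_clb5 = 0.5 * clb5[span].max()
        g1s = _cross_up(t, clb5, half_clb5, w_lo, tp)
        start = _find_start(t, sbf, whi5, w_lo, g1s if g1s is not None else tp)
        cycles.append(CycleRecord(index=k, window=(w_lo, float(tp)),
                                  start_time=start, g1s_time=g1s,
                                  g2m_time=g2m, mexit_time=mexit))

    # trailing partial cycle (covers arrest after the last completed peak)
    tail_lo = float(peak_times[-1])
    if t[-1] - tail_lo > 0:
        span = (t >= tail_lo) & (t <= t[-1])
        half_clb5 = 0.5 * clb5[span].max() if clb5[span].max() > 0 else None
        g1s = (_cross_up(t, clb5, half_clb5, tail_lo, t[-1])
               if half_clb5 else None)
        start = _find_start(t, sbf, whi5, tail_lo,
                            g1s if g1s is not None else t[-1])
        if start is not None or g1s is not None:
            cycles.append(CycleRecord(index=len(cycles),
                                      window=(tail_lo, float(t[-1])),
                                      start_time=start, g1s_time=g1s,
                                      g2m_time=None, mexit_time=None))

    labels = _label_grid(t, cycles)
    return PhaseAnnotation(cycles=tuple(cycles), labels=labels, times=t)


def _label_grid(t, cycles: Sequence[CycleRecord]):
    labels = np.array([PHASE_G1] * t.size, dtype=object)
    for c in cycles:
        if c.g1s_time is not None:
            end = c.g2m_time if c.g2m_time is not None else c.window[1]
            labels[(t >= c.g1s_time) & (t < end)] = PHASE_SG2
        if c.g2m_time is not None:
            end = c.mexit_time if c.mexit_time is not None else c.window[1]
            labels[(t >= c.g2m_time) & (t < end)] = PHASE_M
    return labels


@dataclass(frozen=True)
class ArrestReport:
    """Per-signal-interval arrest verdicts."""

    entries: tuple[dict, ...]

    @property
    def n_arrests(self) -> int:
        return sum(1 for e in self.entries if e["arrested"])


def classify_arrest(annotation: PhaseAnnotation, schedule: SignalSchedule,
                    horizon: float,
                    control: PhaseAnnotation | None = None) -> ArrestReport:
    """Report, per signal interval, whether cycle transitions were blocked.

    An interval counts as arresting when no G1/S transition falls inside it
    (entry into S phase is the checkpoint the two signals guard).  When a
    control annotation of the matching unperturbed run is supplied, the
    delay of the first post-release G1/S transition is reported against the
    control's next G1/S after the same release time.
    """
    g1s = annotation.event_times("g1s")
    g2m = annotation.event_times("g2m")
    entries = []
    for signal, intervals in (("pheromone", schedule.pheromone_intervals),
                              ("osmostress", schedule.osmostress_intervals)):
        for t_on, t_off in intervals:
            if t_on >= horizon:
                continue
            g1s_in = g1s[(g1s >= t_on) & (g1s < min(t_off, horizon))]
            g2m_in = g2m[(g2m >= t_on) & (g2m < min(t_off, horizon))]
            after = g1s[g1s >= t_off]
            entry = {
                "signal": signal,
                "interval": (t_on, t_off),
                "g1s_in_interval": int(g1s_in.size),
                "g2m_in_interval": int(g2m_in.size),
                "arrested": g1s_in.size == 0,
                "first_g1s_after_release": float(after[0]) if after.size else None,
            }
            if control is not None and after.size:
                c_after = control.event_times("g1s")
                c_after = c_after[c_after >= t_off]
                entry["delay_vs_control"] = (
                    float(after[0] - c_after[0]) if c_after.size else None)
            entries.append(entry)
    return ArrestReport(entries=tuple(entries))
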