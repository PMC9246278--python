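"""Cycle metrics: periods, phase durations, oscillation and convergence.

The steady-state protocol mirrors the simulation conventions used
throughout the package: the first ``adaptation_cycles`` completed cycles
are discarded as transient, then at least ten further cycles are measured
when the run is long enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .phase_annotation import PhaseAnnotation
from .simulation import Trajectory

__all__ = ["CycleMetrics", "measure_cycles", "detect_oscillation",
           "OscillationDiagnostics", "limit_cycle_distance"]

DEFAULT_ADAPTATION_CYCLES = 3

# operational definition of stable cycling: at least three successive
# Clb2_total peaks with amplitudes within 20 % of each other and inter-peak
# intervals within 10 %
AMPLITUDE_TOLERANCE = 0.20
INTERVAL_TOLERANCE = 0.10
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class CycleMetrics:
    per_cycle_durations: tuple[float, ...]
    mean_duration: float | None
    n_cycles_used: int
    phase_durations: tuple[dict, ...]
    oscillating: bool
    convergence: tuple[float, ...] = ()

    def summary(self) -> dict:
        return {
            "oscillating": self.oscillating,
            "mean_duration_min": self.mean_duration,
            "n_cycles_used": self.n_cycles_used,
            "duration_cv": (float(np.std(self.per_cycle_durations)
                                  / np.mean(self.per_cycle_durations))
                            if len(self.per_cycle_durations) >= 2 else None),
        }


def measure_cycles(annotation: PhaseAnnotation,
                   adaptation_cycles: int = DEFAULT_ADAPTATION_CYCLES) -> CycleMetrics:
    """START-to-START cycle durations after discarding adaptation cycles."""
    complete = annotation.complete_cycles
    usable = complete[adaptation_cycles:]
    starts = np.array([c.start_time for c in usable])
    if starts.size < 2:
        return CycleMetrics((), None, 0, (), oscillating=False)
    durations = tuple(np.diff(starts).tolist())
    phases = []
    for prev, cur in zip(usable[:-1], usable[1:]):
        phases.append({
            "G1": cur.g1s_time - prev.mexit_time,
            "S/G2": cur.g2m_time - cur.g1s_time,
            "M": cur.mexit_time - cur.g2m_time,
        })
    return CycleMetrics(
        per_cycle_durations=durations,
        mean_duration=float(np.mean(durations)),
        n_cycles_used=len(durations),
        phase_durations=tuple(phases),
        oscillating=True,
    )


@dataclass(frozen=True)
class OscillationDiagnostics:
    oscillating: bool
    peak_times: tuple[float, ...]
    peak_amplitudes: tuple[float, ...]
    reason: str = ""


def detect_oscillation(trajectory: Trajectory, window: float | None = None,
                       signal: str = "Clb2_total") -> OscillationDiagnostics:
    """Stable-cycling test on the tail ``window`` (minutes) of a run."""
    t = trajectory.times
    x = trajectory.column(signal)
    if window is not None:
        mask = t >= t[-1] - window
        t, x = t[mask], x[mask]
    rng = float(x.max() - x.min())
    scale = max(abs(float(x.max())), 1e-12)
    if rng < 1e-3 * scale:
        return OscillationDiagnostics(False, (), (), "signal is constant")
    peaks, _ = find_peaks(x, prominence=PEAK_PROMINENCE_FRACTION * rng)
    if len(peaks) < 3:
        return OscillationDiagnostics(
            False, tuple(t[peaks]), tuple(x[peaks]), "fewer than 3 peaks")
    pt, pa = t[peaks], x[peaks]
    # examine the last three successive peaks
    a = pa[-3:]
    iv = np.diff(pt[-3:])
    amp_ok = (a.max() - a.min()) <= AMPLITUDE_TOLERANCE * a.max()
    int_ok = (iv.max() - iv.min()) <= INTERVAL_TOLERANCE * iv.max()
    reason = "" if (amp_ok and int_ok) else (
        "amplitude drift" if not amp_ok else "interval drift")
    return OscillationDiagnostics(bool(amp_ok and int_ok),
                                  tuple(pt.tolist()), tuple(pa.tolist()), reason)


def limit_cycle_distance(trajectory: Trajectory,
                         projection: tuple[str, str] = ("Cln2_total", "SBF_active"),
                         signal: str = "Clb2_total") -> list[float]:
    """Distances between successive orbits in a 2-D projection.

    Cycles are delimited by minima of ``signal``; the distance between two
    loops is the symmetric mean nearest-point distance between their point
    sets in the projection plane.  A non-increasing sequence indicates
    convergence onto a limit cycle.
    """
    t = trajectory.times
    ref = trajectory.column(signal)
    rng = ref.max() - ref.min()
    if rng <= 0:
        raise ValueError("reference signal is constant; no cycles to compare")
    minima, _ = find_peaks(-ref, prominence=PEAK_PROMINENCE_FRACTION * rng)
    if len(minima) < 4:
        raise ValueError("need at least 3 complete cycles")
    x = trajectory.column(projection[0])
    y = trajectory.column(projection[1])
    loops = []
    for a, b in zip(minima[:-1], minima[1:]):
        loops.append(np.column_stack([x[a:b + 1], y[a:b + 1]]))
    distances = []
    for p, q in zip(loops[:-1], loops[1:]):
        tree_p, tree_q = cKDTree(p), cKDTree(q)
        d_pq = tree_q.query(p)[0].mean()
        d_qp = tree_p.query(q)[0].mean()
        distances.append(float(0.5 * (d_pq + d_qp)))
    return distances
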