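"""Cycle metrics: durations, oscillation detection, orbit convergence."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import yeastcycle as yc
from yeastcycle.cycle_analysis import (
    detect_oscillation,
    limit_cycle_distance,
    measure_cycles,
)
from yeastcycle.model_core import OBSERVABLE_NAMES
from yeastcycle.perturbation import SignalSchedule
from yeastcycle.phase_annotation import CycleRecord, PhaseAnnotation, detect_transitions
from yeastcycle.simulation import IntegratorSettings, Trajectory


def _annotation_from_starts(starts):
    cycles = []
    for i, s in enumerate(starts):
        cycles.append(CycleRecord(index=i, window=(s - 10.0, s + 90.0),
                                  start_time=s, g1s_time=s + 10.0,
                                  g2m_time=s + 50.0, mexit_time=s + 70.0))
    t = np.linspace(0, starts[-1] + 100, 10)
    return PhaseAnnotation(cycles=tuple(cycles),
                           labels=np.array(["G1"] * t.size, dtype=object),
                           times=t)


def _synthetic_trajectory(times, columns):
    obs = pd.DataFrame({name: columns.get(name, np.zeros(times.size))
                        for name in OBSERVABLE_NAMES})
    from yeastcycle._network import SPECIES
    return Trajectory(times=times, states=np.zeros((times.size, 33)),
                      species=tuple(SPECIES), observables=obs,
                      schedule=SignalSchedule(), settings=IntegratorSettings(),
                      event_times=())


class TestMeasureCycles:
    def test_constructed_starts_give_exact_mean(self):
        ann = _annotation_from_starts([0.0, 100.0, 200.0, 300.0, 400.0])
        metrics = measure_cycles(ann, adaptation_cycles=0)
        assert metrics.mean_duration == pytest.approx(100.0)
        assert metrics.n_cycles_used == 4
        assert metrics.oscillating

    def test_adaptation_cycles_discarded(self):
        starts = [0.0, 50.0, 120.0, 220.0, 320.0, 420.0]
        metrics = measure_cycles(_annotation_from_starts(starts),
                                 adaptation_cycles=2)
        assert metrics.mean_duration == pytest.approx(100.0)

    def test_too_few_cycles_flags_non_oscillating(self):
        metrics = measure_cycles(_annotation_from_starts([0.0, 100.0]),
                                 adaptation_cycles=3)
        assert not metrics.oscillating
        assert metrics.per_cycle_durations == ()

    def test_reference_duration_cv_below_half_percent(self, reference_metrics):
        durations = np.array(reference_metrics.per_cycle_durations)
        assert durations.std() / durations.mean() < 0.005

    def test_start_to_start_matches_peak_to_peak(self, reference_trajectory,
                                                 reference_metrics):
        from scipy.signal import find_peaks
        tr = reference_trajectory
        clb2 = tr.column("Clb2_total")
        peaks, _ = find_peaks(clb2, prominence=0.05 * (clb2.max() - clb2.min()))
        intervals = np.diff(tr.times[peaks])[3:]
        assert intervals.mean() == pytest.approx(reference_metrics.mean_duration,
                                                 rel=0.01)

    def test_time_shift_leaves_mean_duration_unchanged(self, model,
                                                       reference_metrics):
        from yeastcycle.experiments import EXPERIMENT_SETTINGS
        # start integration from a state mid-cycle: a non-integer fraction
        # of the period into the orbit
        tr = yc.integrate(model, t_end=1800.0, settings=EXPERIMENT_SETTINGS,
                          initial_state=None)
        i = np.argmin(np.abs(tr.times - 37.0))
        shifted = yc.integrate(model, t_end=1800.0,
                               settings=EXPERIMENT_SETTINGS,
                               initial_state=tr.states[i])
        metrics = measure_cycles(detect_transitions(shifted))
        assert metrics.mean_duration == pytest.approx(
            reference_metrics.mean_duration, rel=0.001)


class TestDetectOscillation:
    def test_reference_run_oscillates(self, reference_trajectory):
        assert detect_oscillation(reference_trajectory).oscillating

    def test_constant_signal_is_not_oscillating(self):
        t = np.linspace(0, 1000, 2001)
        tr = _synthetic_trajectory(t, {"Clb2_total": np.full(t.size, 5.0)})
        diag = detect_oscillation(tr)
        assert not diag.oscillating
        assert diag.reason == "signal is constant"

    def test_damped_oscillation_rejected(self):
        t = np.linspace(0, 1000, 4001)
        # amplitude halves every 100-minute cycle
        signal = 1000.0 * 0.5 ** (t / 100.0) * (1 - np.cos(2 * np.pi * t / 100.0))
        tr = _synthetic_trajectory(t, {"Clb2_total": signal})
        diag = detect_oscillation(tr)
        assert not diag.oscillating
        assert diag.reason == "amplitude drift"


class TestLimitCycleDistance:
    def test_perfectly_periodic_orbit_has_zero_distance(self):
        t = np.linspace(0, 550, 5501)
        clb2 = 100.0 * (1 - np.cos(2 * np.pi * t / 100.0))
        cln2 = 50.0 * (1 - np.sin(2 * np.pi * t / 100.0))
        sbf = 30.0 * (1 + np.cos(2 * np.pi * t / 100.0))
        tr = _synthetic_trajectory(t, {"Clb2_total": clb2,
                                       "Cln2_total": cln2,
                                       "SBF_active": sbf})
        distances = limit_cycle_distance(tr, ("Cln2_total", "SBF_active"))
        assert max(distances) < 1e-6 * 50.0

    def test_reference_orbits_converge(self, reference_trajectory):
        distances = limit_cycle_distance(reference_trajectory,
                                         ("Cln2_total", "SBF_active"))
        # successive-loop distances settle to a tiny fraction of the orbit size
        orbit_scale = reference_trajectory.column("Cln2_total").max()
        assert distances[-1] < 0.01 * orbit_scale
        assert distances[-1] <= distances[0] + 1e-9

    def test_too_few_cycles_raises(self):
        t = np.linspace(0, 120, 1201)
        clb2 = 100.0 * (1 - np.cos(2 * np.pi * t / 100.0))
        tr = _synthetic_trajectory(t, {"Clb2_total": clb2})
        with pytest.raises(ValueError):
            limit_cycle_distance(tr, ("Cln2_total", "SBF_active"))
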