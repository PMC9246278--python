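"""Trajectory integration with event-aware signal switching.

The oscillator itself runs without events; pheromone and osmostress inputs
switch at known clock times.  Integration is therefore split at every switch
time and restarted, so the solver never steps across a discontinuity.  The
default solver is stiff-capable (LSODA) with tight tolerances appropriate
for particle-number state variables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    ModelDefinition,
    OBSERVABLE_NAMES,
    SignalState,
    observable_matrix,
)
from .perturbation import SignalSchedule, signal_at

__all__ = ["IntegratorSettings", "Trajectory", "integrate", "resample"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_OUTPUT_STEP = 0.5


class IntegrationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.6g} min)")
        self.last_time = last_time


@dataclass(frozen=True)
class IntegratorSettings:
    method: str = "LSODA"
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    max_step: float = np.inf


@dataclass(frozen=True)
class Trajectory:
    """Dense solution on a fixed output grid.

    ``states`` is (time x species), ``observables`` (time x derived columns);
    every signal switch time inside the window is a grid point.
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple[str, ...]
    observables: pd.DataFrame
    schedule: SignalSchedule
    settings: IntegratorSettings
    event_times: tuple[float, ...]

    def frame(self) -> pd.DataFrame:
        """Tidy table: time, species columns, observables, signal flags."""
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        for col in self.observables.columns:
            df[col] = self.observables[col].to_numpy()
        df["pheromone_on"] = [signal_at(self.schedule, t).pheromone_on
                              for t in self.times]
        df["osmostress_on"] = [signal_at(self.schedule, t).osmostress_on
                               for t in self.times]
        return df

    def to_csv(self, path) -> None:
        # pandas' default float repr is shortest-round-trip, hence lossless
        self.frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        """A species or observable column by name."""
        if name in self.species:
            return self.states[:, self.species.index(name)]
        return self.observables[name].to_numpy()

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


def _grid(t_start: float, t_end: float, step: float, events) -> np.ndarray:
    base = np.arange(t_start, t_end + 0.5 * step, step)
    base = base[base <= t_end + 1e-12]
    grid = np.union1d(base, np.asarray(events, dtype=float))
    grid = np.union1d(grid, [t_start, t_end])
    return grid[(grid >= t_start - 1e-12) & (grid <= t_end + 1e-12)]


def integrate(model: ModelDefinition, schedule: SignalSchedule | None = None,
              t_end: float = 1220.0, output_step: float = DEFAULT_OUTPUT_STEP,
              t_start: float = 0.0, initial_state=None,
              settings: IntegratorSettings | None = None) -> Trajectory:
    """Integrate the model under a signal schedule.

    The window ``[t_start, t_end]`` is split at every signal switch time and
    the solver restarted from the previous endpoint, so discontinuous inputs
    are handled exactly.  Deterministic: identical inputs and settings give
    identical trajectories.
    """
    if schedule is None:
        schedule = SignalSchedule()
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if not output_step > 0:
        raise ValueError("output_step must be positive")
    settings = settings or IntegratorSettings()

    events = schedule.switch_times(t_start, t_end)
    grid = _grid(t_start, t_end, output_step, events)
    y0 = np.asarray(model.initial_state if initial_state is None else initial_state,
                    dtype=float)
    if y0.shape != (model.n_species,):
        raise ValueError("initial state has wrong dimension")

    segment_bounds = [t_start, *events, t_end]
    states = np.empty((grid.size, model.n_species))
    states[0] = y0
    filled = 1

    y = y0
    for seg_start, seg_end in zip(segment_bounds, segment_bounds[1:]):
        # signal state is constant on [seg_start, seg_end); evaluate just
        # inside the segment
        sig = signal_at(schedule, seg_start)

        def f(t, yy, _sig=sig):
            return model.rhs_unchecked(yy, _sig)

        mask = (grid > seg_start + 1e-12) & (grid <= seg_end + 1e-12)
        t_eval = grid[mask]
        sol = solve_ivp(f, (seg_start, seg_end), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        max_step=settings.max_step, t_eval=t_eval,
                        dense_output=False)
        if not sol.success:
            last = sol.t[-1] if sol.t.size else seg_start
            raise IntegrationError(f"integrator failed: {sol.message}", last)
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError("non-finite state encountered", seg_start)
        n = sol.t.size
        states[filled:filled + n] = sol.y.T
        filled += n
        # restart from the exact segment endpoint
        y = states[filled - 1] if n else y

    assert filled == grid.size
    obs = pd.DataFrame(states @ observable_matrix(model).T,
                       columns=list(OBSERVABLE_NAMES))
    return Trajectory(times=grid, states=states, species=model.inventory.names,
                      observables=obs, schedule=schedule, settings=settings,
                      event_times=events)


def resample(trajectory: Trajectory, new_step: float) -> Trajectory:
    """Linear interpolation onto a new uniform grid (event times kept)."""
    if not new_step > 0:
        raise ValueError("new_step must be positive")
    grid = _grid(trajectory.t_start, trajectory.t_end, new_step,
                 trajectory.event_times)
    states = np.empty((grid.size, trajectory.states.shape[1]))
    for j in range(trajectory.states.shape[1]):
        states[:, j] = np.interp(grid, trajectory.times, trajectory.states[:, j])
    obs = np.empty((grid.size, trajectory.observables.shape[1]))
    for j, col in enumerate(trajectory.observables.columns):
        obs[:, j] = np.interp(grid, trajectory.times,
                              trajectory.observables[col].to_numpy())
    return replace(trajectory, times=grid, states=states,
                   observables=pd.DataFrame(obs, columns=list(trajectory.observables.columns)))


def read_trajectory_csv(path, schedule: SignalSchedule | None = None) -> Trajectory:
    """Read a trajectory written by :meth:`Trajectory.to_csv`.

    The signal flags in the file are informational; pass the original
    schedule to restore it exactly.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    from ._network import SPECIES

    species = tuple(s for s in SPECIES if s in df.columns)
    obs_cols = [c for c in OBSERVABLE_NAMES if c in df.columns]
    times = df["time"].to_numpy(dtype=float)
    schedule = schedule or SignalSchedule()
    return Trajectory(
        times=times,
        states=df[list(species)].to_numpy(dtype=float),
        species=species,
        observables=df[obs_cols].copy(),
        schedule=schedule,
        settings=IntegratorSettings(),
        event_times=schedule.switch_times(times[0], times[-1]),
    )
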