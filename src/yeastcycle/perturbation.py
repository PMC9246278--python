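"""Physiological input schedules: pheromone, osmotic stress, nutrition.

Signals are binary and switched instantaneously at scheduled clock times
(the MAPK cascades upstream of Fus3 and Hog1 are not modelled).  Intervals
follow the half-open convention ``[t_on, t_off)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelDefinition, ParameterSet, SignalState

__all__ = [
    "SignalSchedule",
    "signal_at",
    "apply_nutrition",
    "pheromone_terms",
    "hog1_terms",
]


def _validate_intervals(intervals, label):
    out = []
    for pair in intervals:
        t_on, t_off = float(pair[0]), float(pair[1])
        if t_on < 0 or not t_on < t_off:
            raise ValueError(f"{label} interval [{t_on}, {t_off}) is invalid")
        out.append((t_on, t_off))
    out.sort()
    for (a0, a1), (b0, _) in zip(out, out[1:]):
        if b0 < a1:
            raise ValueError(f"{label} intervals overlap at t={b0}")
    return tuple(out)


@dataclass(frozen=True)
class SignalSchedule:
    """On/off intervals (minutes) per signal plus a constant nutrition factor."""

    pheromone_intervals: tuple[tuple[float, float], ...] = ()
    osmostress_intervals: tuple[tuple[float, float], ...] = ()
    nutrition_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "pheromone_intervals",
                           _validate_intervals(self.pheromone_intervals, "pheromone"))
        object.__setattr__(self, "osmostress_intervals",
                           _validate_intervals(self.osmostress_intervals, "osmostress"))
        if not (np.isfinite(self.nutrition_factor) and self.nutrition_factor > 0):
            raise ValueError("nutrition_factor must be positive and finite")

    def switch_times(self, t_start: float, t_end: float) -> tuple[float, ...]:
        """All signal on/off times strictly inside ``(t_start, t_end)``."""
        times = set()
        for intervals in (self.pheromone_intervals, self.osmostress_intervals):
            for t_on, t_off in intervals:
                for t in (t_on, t_off):
                    if t_start < t < t_end:
                        times.add(t)
        return tuple(sorted(times))


def _active(intervals, t: float) -> bool:
    for t_on, t_off in intervals:
        if t_on <= t < t_off:
            return True
    return False


def signal_at(schedule: SignalSchedule, t: float) -> SignalState:
    """Signal state at time ``t`` (half-open intervals: on at t_on, off at t_off)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return SignalState(
        pheromone_on=_active(schedule.pheromone_intervals, t),
        osmostress_on=_active(schedule.osmostress_intervals, t),
        nutrition_factor=schedule.nutrition_factor,
    )


def apply_nutrition(params: ParameterSet, factor: float) -> ParameterSet:
    """Scale every protein-production rate constant by ``factor``.

    Pure function: the input set is left untouched.  This is the model's
    nutrition interface — a global modulation of biosynthetic capacity.
    """
    if not (np.isfinite(factor) and factor > 0):
        raise ValueError("nutrition factor must be positive and finite")
    scaled = {
        name: (value * factor if name in params.production_subset else value)
        for name, value in params.values.items()
    }
    return ParameterSet(scaled, params.production_subset)


def _signal_difference(model: ModelDefinition, state, on: SignalState,
                       off: SignalState) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    return model.rhs_unchecked(state, on) - model.rhs_unchecked(state, off)


def pheromone_terms(model: ModelDefinition, state, params=None,
                    pheromone_on: bool = True) -> np.ndarray:
    """Pheromone-specific rate contributions at ``state``.

    Returns the derivative difference between the given pheromone state and
    the reference (pheromone off).  When ``pheromone_on`` is False this is
    identically zero: Fus3-dependent Far1 induction and stabilisation act
    only under signal, while Cln2-mediated Far1 degradation is always on.
    """
    if params is not None:
        model = model.with_parameters(params)
    on = SignalState(pheromone_on=bool(pheromone_on))
    return _signal_difference(model, state, on, SignalState())


def hog1_terms(model: ModelDefinition, state, params=None,
               osmostress_on: bool = True) -> np.ndarray:
    """Hog1-specific rate contributions at ``state``.

    Under osmostress the Cln1/2 and Clb5/6 expression rates are scaled down,
    Sic1 is converted to its stabilised Thr173 phosphoform, and the
    Clb2-mediated Swe1 phosphorylation is inhibited.  With the signal off
    the contribution vector is identically zero.
    """
    if params is not None:
        model = model.with_parameters(params)
    on = SignalState(osmostress_on=bool(osmostress_on))
    return _signal_difference(model, state, on, SignalState())
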