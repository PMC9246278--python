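"""Model definition and right-hand side of the 33-species cell cycle ODE.

The model describes the autonomous cyclin/CDK oscillator of budding yeast in
particle numbers (molecules per cell) and minutes.  Three input signals feed
into the right-hand side: active Fus3 (pheromone), active Hog1 (osmostress)
and a scalar nutrition factor that multiplies every protein-production rate
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _network
from ._network import (
    N_PARAMETERS,
    N_SPECIES,
    PARAMETERS,
    PARAMETER_INDEX,
    POOLS,
    PRODUCTION_PARAMETERS,
    REACTIONS,
    SPECIES,
    SPECIES_INDEX,
    SPECIES_TABLE,
)

__all__ = [
    "SpeciesRecord",
    "SpeciesInventory",
    "ParameterSet",
    "SignalState",
    "Reaction",
    "ModelDefinition",
    "build_reference_model",
    "rhs",
    "conserved_totals",
    "derived_observables",
    "OBSERVABLE_NAMES",
]


class ModelDefinitionError(ValueError):
    """A structural inconsistency in a model definition."""


@dataclass(frozen=True)
class SpeciesRecord:
    name: str
    role: str
    pools: tuple[str, ...] = ()
    constituents: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpeciesInventory:
    entries: tuple[SpeciesRecord, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ModelDefinitionError("duplicate species names")
        for entry in self.entries:
            for part in entry.constituents:
                if part not in names:
                    raise ModelDefinitionError(
                        f"complex {entry.name} names unknown constituent {part}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ParameterSet:
    """Named nonnegative rate constants plus the protein-production subset.

    ``production_subset`` marks the :math:`k_p` parameters that the nutrition
    factor scales.
    """

    values: Mapping[str, float]
    production_subset: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "production_subset", frozenset(self.production_subset))
        if not self.production_subset:
            raise ModelDefinitionError("production subset is empty")
        if not self.production_subset < set(self.values):
            raise ModelDefinitionError(
                "production subset must be a strict subset of all parameters"
            )
        for name, value in self.values.items():
            if not np.isfinite(value) or value < 0:
                raise ModelDefinitionError(
                    f"parameter {name} = {value!r} is not finite and nonnegative"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def replace(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        merged = {**self.values, **updates}
        return ParameterSet(merged, self.production_subset)

    def to_array(self, order: Sequence[str] = PARAMETERS) -> np.ndarray:
        return np.array([self.values[name] for name in order], dtype=float)


@dataclass(frozen=True)
class SignalState:
    """Instantaneous physiological inputs.

    The default ``SignalState()`` (both MAPKs off, nutrition factor 1.0) is
    the reference condition.
    """

    pheromone_on: bool = False
    osmostress_on: bool = False
    nutrition_factor: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.nutrition_factor) and self.nutrition_factor > 0):
            raise ValueError("nutrition_factor must be a positive finite number")


@dataclass(frozen=True)
class Reaction:
    name: str
    stoichiometry: Mapping[str, int]
    rate: str

    @property
    def reactants(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(s for s, c in self.stoichiometry.items() if c > 0)


@dataclass(frozen=True)
class ModelDefinition:
    """The complete 33-ODE system: structure, kinetics and reference state."""

    inventory: SpeciesInventory
    parameters: ParameterSet
    rate_laws: tuple[Reaction, ...]
    conservation_pools: Mapping[str, tuple[str, ...]]
    initial_state: np.ndarray
    _rates_fn: object = field(default=None, repr=False, compare=False)
    _stoich: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "initial_state",
                           np.asarray(self.initial_state, dtype=float))
        if self.initial_state.shape != (len(self.inventory),):
            raise ModelDefinitionError("initial state has wrong dimension")
        if np.any(self.initial_state < 0) or not np.all(np.isfinite(self.initial_state)):
            raise ModelDefinitionError("initial state must be finite and nonnegative")
        names = set(self.inventory.names)
        for reaction in self.rate_laws:
            for species in reaction.stoichiometry:
                if species not in names:
                    raise ModelDefinitionError(
                        f"reaction {reaction.name} references unknown species {species}"
                    )
        for pool, members in self.conservation_pools.items():
            for member in members:
                if member not in names:
                    raise ModelDefinitionError(
                        f"pool {pool} references unknown species {member}"
                    )
            # conservation by construction: each rate law must leave the pool sum
            # unchanged
            for reaction in self.rate_laws:
                net = sum(reaction.stoichiometry.get(m, 0) for m in members)
                if net != 0:
                    raise ModelDefinitionError(
                        f"reaction {reaction.name} changes conserved pool {pool}"
                    )

    @property
    def n_species(self) -> int:
        return len(self.inventory)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def with_parameters(self, parameters: ParameterSet) -> "ModelDefinition":
        return replace(self, parameters=parameters)

    def with_initial_state(self, state: np.ndarray) -> "ModelDefinition":
        return replace(self, initial_state=np.asarray(state, dtype=float))

    # -- evaluation -----------------------------------------------------------

    @property
    def parameter_order(self) -> tuple[str, ...]:
        return tuple(self.parameters.values)

    def _compiled(self):
        fn = self._rates_fn
        if fn is None:
            names = self.inventory.names
            fn = _network.compile_rates(
                species=names,
                parameters=self.parameter_order,
                expressions=[r.rate for r in self.rate_laws],
            )
            stoich = np.zeros((len(names), len(self.rate_laws)))
            index = {n: i for i, n in enumerate(names)}
            for j, reaction in enumerate(self.rate_laws):
                for sp, coeff in reaction.stoichiometry.items():
                    stoich[index[sp], j] = coeff
            object.__setattr__(self, "_rates_fn", fn)
            object.__setattr__(self, "_stoich", stoich)
        return self._rates_fn, self._stoich

    def reaction_rates(self, state, signals: SignalState) -> np.ndarray:
        fn, _ = self._compiled()
        p = self.parameters.to_array(self.parameter_order)
        return fn(np.asarray(state, dtype=float), p,
                  float(signals.pheromone_on), float(signals.osmostress_on),
                  signals.nutrition_factor)

    def rhs_unchecked(self, state, signals: SignalState) -> np.ndarray:
        """Derivative without input validation (integrator fast path)."""
        fn, stoich = self._compiled()
        p = self.parameters.to_array(self.parameter_order)
        v = fn(state, p, float(signals.pheromone_on),
               float(signals.osmostress_on), signals.nutrition_factor)
        return stoich @ v


def build_reference_model() -> ModelDefinition:
    """Assemble the reference model: 33 species, 111 calibrated parameters.

    Parameter values and the reference initial state are loaded from the
    plain-text tables bundled with the package (``data/parameters.csv``,
    ``data/initial_state.csv``).
    """
    from . import _reference_data

    inventory = SpeciesInventory(tuple(
        SpeciesRecord(name, role, tuple(pools), tuple(parts))
        for name, role, pools, parts in SPECIES_TABLE
    ))
    values = _reference_data.load_parameters()
    missing = set(PARAMETERS) - set(values)
    extra = set(values) - set(PARAMETERS)
    if missing or extra:
        raise ModelDefinitionError(
            f"parameter table mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    parameters = ParameterSet(values, frozenset(PRODUCTION_PARAMETERS))
    initial = _reference_data.load_initial_state()
    state = np.array([initial[name] for name in SPECIES], dtype=float)
    rate_laws = tuple(Reaction(name, dict(stoich), expr)
                      for name, stoich, expr in REACTIONS)
    return ModelDefinition(
        inventory=inventory,
        parameters=parameters,
        rate_laws=rate_laws,
        conservation_pools={k: tuple(v) for k, v in POOLS.items()},
        initial_state=state,
    )


def rhs(model: ModelDefinition, state, signals: SignalState | None = None,
        t: float = 0.0) -> np.ndarray:
    """Evaluate d(state)/dt at ``state`` under the given signals.

    Negative or non-finite state components are rejected (not clamped): a
    state that has left the nonnegative orthant indicates an integration
    problem that must not be masked.
    """
    del t  # the system is autonomous; signals carry all time dependence
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({model.n_species},)"
        )
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite components")
    if np.any(state < 0):
        bad = [model.inventory.names[i] for i in np.nonzero(state < 0)[0]]
        raise ValueError(f"state contains negative components: {bad}")
    if signals is None:
        signals = SignalState()
    return model.rhs_unchecked(state, signals)


def conserved_totals(model: ModelDefinition, state,
                     pools: Iterable[str] | None = None) -> dict[str, float]:
    """Current total of each conservation pool (sum over member species)."""
    state = np.asarray(state, dtype=float)
    names = model.inventory.names
    result = {}
    for pool in (pools if pools is not None else model.conservation_pools):
        try:
            members = model.conservation_pools[pool]
        except KeyError:
            raise KeyError(f"unknown conservation pool {pool!r}") from None
        result[pool] = float(sum(state[names.index(m)] for m in members))
    return result


# derived observables: totals across complexes/phosphoforms plus the
# active/inactive splits used for phase annotation (Fig-3-style bookkeeping)
_OBSERVABLE_DEFS = {
    "Sic1_total": ("Sic1", "Sic1_p", "Sic1_Hp", "Clb5_Sic1", "Clb5_Sic1_Hp",
                   "Clb3_Sic1", "Clb2_Sic1"),
    "Clb5_total": ("Clb5", "Clb5_Sic1", "Clb5_Sic1_Hp"),
    "Clb3_total": ("Clb3", "Clb3_Sic1"),
    "Clb2_total": ("Clb2", "Clb2_p", "Clb2_Sic1"),
    "Cln2_total": ("Cln2", "Cln2_Far1_p"),
    "Cln3_total": ("Cln3", "Cln3_Far1_p"),
    "Far1_total": ("Far1", "Far1_p", "Cln2_Far1_p", "Cln3_Far1_p"),
    "Whi5_nuclear": ("Whi5", "SBF_Whi5"),
    "Swe1_total": ("Swe1", "Swe1_p"),
    "Clb5_active": ("Clb5",),
    "Clb2_active": ("Clb2",),
    "Clb5_inactive": ("Clb5_Sic1", "Clb5_Sic1_Hp"),
    "Clb2_inactive": ("Clb2_p", "Clb2_Sic1"),
    "SBF_active": ("SBF",),
}

OBSERVABLE_NAMES = tuple(_OBSERVABLE_DEFS)

_OBSERVABLE_MATRIX = np.zeros((len(_OBSERVABLE_DEFS), N_SPECIES))
for _i, _members in enumerate(_OBSERVABLE_DEFS.values()):
    for _m in _members:
        _OBSERVABLE_MATRIX[_i, SPECIES_INDEX[_m]] = 1.0


def derived_observables(model: ModelDefinition, state) -> dict[str, float]:
    """Totals and active/inactive splits derived from a single state vector."""
    state = np.asarray(state, dtype=float)
    values = observable_matrix(model) @ state
    return dict(zip(OBSERVABLE_NAMES, values.tolist()))


def observable_matrix(model: ModelDefinition) -> np.ndarray:
    """Linear map from the species vector to the derived observables."""
    if model.inventory.names != tuple(SPECIES):
        # general fallback for models with re-ordered inventories
        mat = np.zeros((len(_OBSERVABLE_DEFS), len(model.inventory)))
        for i, members in enumerate(_OBSERVABLE_DEFS.values()):
            for m in members:
                mat[i, model.inventory.index(m)] = 1.0
        return mat
    return _OBSERVABLE_MATRIX
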