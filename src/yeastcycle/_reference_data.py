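"""Loaders for the bundled reference parameter set and initial state.

The reference constants live in two plain-text CSV tables under
``yeastcycle/data/``.  They are this package's own calibration of the
33-species network: values were adjusted iteratively against the published
behaviour of the system (stable limit-cycle oscillation, a reference cycle
duration near 122 minutes with realistic phase lengths, particle numbers on
the scale of measured whole-cell protein abundances, and the documented
responses to pheromone, osmotic stress and nutrition changes).
"""

from __future__ import annotations

import csv
from importlib import resources


def _read_table(filename: str) -> dict[str, float]:
    path = resources.files("yeastcycle.data").joinpath(filename)
    out: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            out[row["name"]] = float(row["value"])
    return out


def load_parameters() -> dict[str, float]:
    """Parameter name -> value (particle numbers and minutes)."""
    return _read_table("parameters.csv")


def load_initial_state() -> dict[str, float]:
    """Species name -> reference initial particle number."""
    return _read_table("initial_state.csv")
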