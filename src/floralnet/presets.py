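"""Packaged reference parameter set and named presets.

The ``reference`` preset is the kinetic set identified from the floral
meristem expression time series (maximal transcription rates beta in
nM/day, half-maximal constants Km in nM, decay rates dc in 1/day, trigger
magnitudes P2/P4 in nM/day), slot-aligned with the default topology.
"""

from __future__ import annotations

from .network import (
    KineticParameters,
    NetworkTopology,
    build_default_topology,
)

__all__ = ["reference_parameters", "reference_system", "PRESETS"]


def reference_parameters() -> KineticParameters:
    """The identified reference kinetic set for the default topology.

    Slot k of gene i carries the pair (beta_{i,k}, Km_{i,k}); repressor
    constants follow the activator slots (e.g. Km_{1,2} is AP1's [AG AG]
    repression constant, Km_{4,3} is AG's [AP1 AP1] constant).
    """
    return KineticParameters(
        beta={
            "AP1": (6.6e4,),
            "AP3": (3.3e4, 1.2e2, 1.2e2),
            "PI": (1.5e3, 38.0, 38.0),
            "AG": (8.8e3, 1.5e4),
            "SHP": (4.1e2,),
            "SEP": (2.3e3, 44.0, 6.0e3),
        },
        km_act={
            "AP1": (10.0,),
            "AP3": (6.1e2, 1.1e3, 1.1e2),
            "PI": (3.1e2, 6.3e2, 63.0),
            "AG": (10.0, 1.0e2),
            "SHP": (1.0e3,),
            "SEP": (5.7e2, 20.0, 47.0),
        },
        km_rep={
            "AP1": (3.7e2,),
            "AP3": (),
            "PI": (),
            "AG": (1.1e3,),
            "SHP": (10.0,),
            "SEP": (),
        },
        dc={"AP1": 71.0, "AP3": 3.0, "PI": 48.0, "AG": 5.0e2, "SHP": 4.0, "SEP": 16.0},
        p2_magnitude=4.5e4,
        p4_magnitude=3.4e3,
    )


def reference_system() -> tuple[NetworkTopology, KineticParameters]:
    """Default topology plus the reference kinetic set, validated."""
    topology = build_default_topology()
    params = reference_parameters()
    params.validate(topology)
    return topology, params


PRESETS = {"reference": reference_parameters}
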