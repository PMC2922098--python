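"""In-silico experiments: wild type, mutants, dimer knockouts, robustness.

Organ identity follows the ABCDE map on day-5 expression: sepal = A+E,
petal = A+B+E, stamen = B+C+E, carpel = C+E (D marks ovule/D-function
within the carpel programme), where A=AP1, B=AP3 and PI jointly (the
obligate [AP3 PI] heterodimer), C=AG, D=SHP, E=SEP.  A whorl whose on/off
vector matches none of the four patterns — in particular any whorl without
E function — develops no floral organ.

A gene counts as "on" in a whorl when its day-5 total (monomer plus
dimer-bound) concentration exceeds a per-gene threshold referenced to the
wild type: threshold_g = max(floor, frac * max over whorls of the
wild-type day-5 total of g).  The relative form mirrors how expression
states are read off fitted trajectories (a gene an order of magnitude
below its own on-level is off, whatever its absolute value); the floor
handles genes that never come on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import (
    GENE_INDEX,
    GENES,
    KineticParameters,
    NetworkTopology,
    Trajectory,
    TriggerSchedule,
)
from .qss import simulate_reduced
from .synth import SyntheticConfig, initial_monomers
from .transform import WHORLS, ConcentrationGrid

__all__ = [
    "ThresholdPolicy",
    "OrganCall",
    "MutantSpec",
    "MutantResult",
    "ScreenRow",
    "WILD_TYPE_CALLS",
    "LITERATURE_MUTANTS",
    "classify_organs",
    "reference_thresholds",
    "run_mutant",
    "dimer_knockout_screen",
    "mean_relative_error",
    "gamma_robustness",
    "gamma_robustness_refit",
    "literature_concordance",
]

WILD_TYPE_CALLS: dict[int, str] = {1: "sepal", 2: "petal", 3: "stamen", 4: "carpel"}

#: Per-whorl phenotypes of the five literature mutants (whorls 1-4).
LITERATURE_MUTANTS: dict[str, tuple[str, str, str, str]] = {
    "ap3-ko": ("sepal", "sepal", "carpel", "carpel"),
    "pi-ko": ("sepal", "sepal", "carpel", "carpel"),
    "ap3-oe": ("sepal", "petal", "stamen", "stamen"),
    "ag-oe": ("carpel", "stamen", "stamen", "carpel"),
    "ag-ko": ("sepal", "petal", "petal", "sepal"),
}

_LABELS = {
    (True, False, False, True): "sepal",
    (True, True, False, True): "petal",
    (False, True, True, True): "stamen",
    (False, False, True, True): "carpel",
}


@dataclass(frozen=True)
class ThresholdPolicy:
    """On/off calling policy: relative fraction of the wild-type on-level
    per gene, with an absolute floor (nM, total concentration)."""

    rel_fraction: float = 0.1
    floor: float = 100.0
    representation: str = "total"
    day: float = 5.0

    def thresholds(self, reference: Mapping[str, float]) -> dict[str, float]:
        return {
            g: max(self.floor, self.rel_fraction * reference.get(g, 0.0))
            for g in GENES
        }


@dataclass
class OrganCall:
    """Per-whorl organ label with the gene on/off vector behind it."""

    whorl: int
    label: str
    on: dict[str, bool]
    day: float

    @property
    def abc_state(self) -> tuple[bool, bool, bool, bool]:
        """(A, B, C, E) with B requiring both AP3 and PI."""
        return (
            self.on["AP1"],
            self.on["AP3"] and self.on["PI"],
            self.on["AG"],
            self.on["SEP"],
        )


@dataclass(frozen=True)
class MutantSpec:
    """A simulated genetic perturbation.

    kinds: ``wild_type``; ``knockout`` (zero initial concentration and
    zero production, trigger included, for a gene); ``ectopic`` (gene
    concentration pinned at ``ectopic_level`` in all whorls);
    ``dimer_removal`` (one dimer's affinity ratio set to zero).
    """

    kind: str = "wild_type"
    target: str | None = None
    ectopic_level: float = 1.0e4

    def __post_init__(self) -> None:
        if self.kind not in {"wild_type", "knockout", "ectopic", "dimer_removal"}:
            raise ValueError(f"unknown mutant kind {self.kind!r}")
        if self.kind in {"knockout", "ectopic"} and self.target not in GENES:
            raise ValueError(f"{self.kind} needs a gene target, got {self.target!r}")
        if self.kind == "dimer_removal" and self.target is None:
            raise ValueError("dimer_removal needs a dimer name target")


@dataclass
class MutantResult:
    spec: MutantSpec
    trajectories: dict[int, Trajectory]
    calls: dict[int, OrganCall]
    changed_whorls: tuple[int, ...]
    thresholds: dict[str, float]


@dataclass
class ScreenRow:
    """One dimer-removal prediction of the seven-dimer screen."""

    dimer: str
    calls: dict[int, str]
    conversions: dict[int, tuple[str, str]]  # whorl -> (wild type, mutant)
    n_organ_conversions: int  # conversions to another organ (not "none")
    double_conversion: bool
    altered: bool
    d_function_lost: bool = False


def _day_index(traj: Trajectory, day: float) -> int:
    return traj.at_time(day)


def classify_organs(
    trajectories: Mapping[int, Trajectory],
    thresholds: Mapping[str, float],
    policy: ThresholdPolicy | None = None,
) -> dict[int, OrganCall]:
    """Call the organ identity of each whorl at the evaluation day."""
    policy = policy or ThresholdPolicy()
    calls: dict[int, OrganCall] = {}
    for w, traj in trajectories.items():
        idx = _day_index(traj, policy.day)
        on = {
            g: bool(traj.gene(g, policy.representation)[idx] >= thresholds[g])
            for g in GENES
        }
        label = _LABELS.get(
            (on["AP1"], on["AP3"] and on["PI"], on["AG"], on["SEP"]), "none"
        )
        calls[w] = OrganCall(whorl=w, label=label, on=on, day=policy.day)
    return calls


def reference_thresholds(
    wild_type: Mapping[int, Trajectory], policy: ThresholdPolicy | None = None
) -> dict[str, float]:
    """Per-gene thresholds from a wild-type run (cross-whorl day-5 maxima)."""
    policy = policy or ThresholdPolicy()
    ref = {}
    for g in GENES:
        ref[g] = max(
            float(traj.gene(g, policy.representation)[_day_index(traj, policy.day)])
            for traj in wild_type.values()
        )
    return policy.thresholds(ref)


def _apply_mutation(
    spec: MutantSpec,
    topology: NetworkTopology,
    params: KineticParameters,
    x0: np.ndarray,
) -> tuple[NetworkTopology, KineticParameters, np.ndarray, dict[int, float] | None]:
    params = params.copy()
    x0 = x0.copy()
    pinned = None
    if spec.kind == "knockout":
        i = GENE_INDEX[spec.target] - 1
        tiny = 1e-30  # production is structurally zero; keep validation happy
        params.beta[spec.target] = tuple(tiny for _ in params.beta[spec.target])
        if spec.target == "AP3":
            params.p2_magnitude = tiny
        elif spec.target == "AG":
            params.p4_magnitude = tiny
        x0[i] = 0.0
    elif spec.kind == "ectopic":
        i = GENE_INDEX[spec.target] - 1
        pinned = {i: spec.ectopic_level}
    elif spec.kind == "dimer_removal":
        topology = topology.with_gamma({spec.target: 0.0})
    return topology, params, x0, pinned


def run_mutant(
    spec: MutantSpec,
    topology: NetworkTopology | None = None,
    params: KineticParameters | None = None,
    schedule: TriggerSchedule | None = None,
    policy: ThresholdPolicy | None = None,
    thresholds: Mapping[str, float] | None = None,
    t_end: float = 5.0,
    t_eval: np.ndarray | None = None,
) -> MutantResult:
    """Simulate a perturbed flower and compare organ calls to wild type.

    Thresholds default to the wild-type-referenced policy computed from an
    unperturbed run of the same system.
    """
    config = SyntheticConfig(topology=topology, params=params,
                             schedule=schedule or TriggerSchedule())
    topology, params, schedule = config.topology, config.params, config.schedule
    policy = policy or ThresholdPolicy()
    x0 = initial_monomers(config)
    if t_eval is None:
        t_eval = np.arange(0.0, t_end + 1e-9, 0.05)

    def run(top, par, x_init, pinned):
        return {
            w: simulate_reduced(x_init, (0.0, t_end), w, top, par, schedule,
                                t_eval=t_eval, pinned=pinned)
            for w in WHORLS
        }

    if thresholds is None:
        wild = run(topology, params, x0, None)
        thresholds = reference_thresholds(wild, policy)
    else:
        wild = None
        thresholds = dict(thresholds)

    if spec.kind == "wild_type":
        trajectories = wild if wild is not None else run(topology, params, x0, None)
    else:
        top_m, par_m, x0_m, pinned = _apply_mutation(spec, topology, params, x0)
        trajectories = run(top_m, par_m, x0_m, pinned)

    calls = classify_organs(trajectories, thresholds, policy)
    changed = tuple(w for w in WHORLS if calls[w].label != WILD_TYPE_CALLS[w])
    return MutantResult(spec=spec, trajectories=trajectories, calls=calls,
                        changed_whorls=changed, thresholds=dict(thresholds))


def dimer_knockout_screen(
    topology: NetworkTopology | None = None,
    params: KineticParameters | None = None,
    schedule: TriggerSchedule | None = None,
    policy: ThresholdPolicy | None = None,
) -> list[ScreenRow]:
    """Remove each dimer in turn (gamma -> 0) and predict the phenotype.

    A "double organ conversion" is exactly two whorls changing to another
    organ label (not "none").  Removal of [SHP SEP] cannot change a
    four-label call — SHP regulates nothing downstream — so the screen
    additionally reports loss of D function: the carpel whorl keeps its
    label while SHP's dimer-bound day-5 level falls below threshold.
    """
    config = SyntheticConfig(topology=topology, params=params,
                             schedule=schedule or TriggerSchedule())
    topology, params, schedule = config.topology, config.params, config.schedule
    policy = policy or ThresholdPolicy()
    wild = run_mutant(MutantSpec(kind="wild_type"), topology, params, schedule, policy)
    rows: list[ScreenRow] = []
    for spec_d in topology.dimers:
        result = run_mutant(
            MutantSpec(kind="dimer_removal", target=spec_d.name),
            topology, params, schedule, policy, thresholds=wild.thresholds,
        )
        conversions = {
            w: (WILD_TYPE_CALLS[w], result.calls[w].label)
            for w in result.changed_whorls
        }
        n_organ = sum(1 for _, new in conversions.values() if new != "none")
        d_lost = False
        if not conversions:
            # D-function check on the unchanged carpel whorl
            for w in WHORLS:
                if result.calls[w].label == "carpel":
                    traj = result.trajectories[w]
                    bound = traj.gene("SHP", "bound")[_day_index(traj, policy.day)]
                    if bound < result.thresholds["SHP"]:
                        d_lost = True
        rows.append(
            ScreenRow(
                dimer=spec_d.name,
                calls={w: result.calls[w].label for w in WHORLS},
                conversions=conversions,
                n_organ_conversions=n_organ,
                double_conversion=(n_organ == 2),
                altered=bool(conversions) or d_lost,
                d_function_lost=d_lost,
            )
        )
    return rows


def mean_relative_error(
    sim: ConcentrationGrid,
    data: ConcentrationGrid,
    days: Sequence[float] | None = None,
) -> np.ndarray:
    """Signed mean relative error per (gene, whorl), shape (6, 4).

    eps = mean_i (x(t_i) - x_d(t_i)) / x_d(t_i): deliberately not squared,
    so a systematic over- or underestimation keeps its sign; normalization
    by the data makes different concentration scales comparable.
    """
    if sim.days != data.days:
        raise ValueError("sim and data must share the same day grid")
    sel = [i for i, d in enumerate(data.days) if days is None or d in days]
    if (data.values[:, :, sel] <= 0).any():
        raise ValueError("data values must be strictly positive")
    diff = (sim.values[:, :, sel] - data.values[:, :, sel]) / data.values[:, :, sel]
    return diff.mean(axis=2)


@dataclass
class RobustnessEntry:
    dimer: str
    factor: float
    calls_unchanged: bool
    max_relative_deviation: float


def gamma_robustness(
    topology: NetworkTopology | None = None,
    params: KineticParameters | None = None,
    schedule: TriggerSchedule | None = None,
    factor: float = 2.0,
    policy: ThresholdPolicy | None = None,
) -> list[RobustnessEntry]:
    """Scale each affinity ratio by ``factor`` and 1/``factor`` in turn.

    Reports whether all four wild-type organ calls survive (against the
    nominal wild-type thresholds) and the largest relative deviation of
    any day-5 total from its nominal value.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    config = SyntheticConfig(topology=topology, params=params,
                             schedule=schedule or TriggerSchedule())
    topology, params, schedule = config.topology, config.params, config.schedule
    policy = policy or ThresholdPolicy()
    wild = run_mutant(MutantSpec(kind="wild_type"), topology, params, schedule, policy)
    day = policy.day
    nominal = {
        w: wild.trajectories[w].totals()[_day_index(wild.trajectories[w], day)]
        for w in WHORLS
    }
    entries: list[RobustnessEntry] = []
    for spec_d in topology.dimers:
        for f in (factor, 1.0 / factor):
            perturbed = topology.scaled_gamma(spec_d.name, f)
            # classify against the perturbed system's own wild-type
            # reference: the question is whether the *pattern* survives
            result = run_mutant(
                MutantSpec(kind="wild_type"), perturbed, params, schedule, policy,
            )
            unchanged = all(
                result.calls[w].label == WILD_TYPE_CALLS[w] for w in WHORLS
            )
            dev = 0.0
            for w in WHORLS:
                tot = result.trajectories[w].totals()[
                    _day_index(result.trajectories[w], day)
                ]
                with np.errstate(divide="ignore", invalid="ignore"):
                    rel = np.abs(tot - nominal[w]) / np.where(nominal[w] > 0,
                                                              nominal[w], 1.0)
                dev = max(dev, float(np.max(rel)))
            entries.append(RobustnessEntry(dimer=spec_d.name, factor=f,
                                           calls_unchanged=unchanged,
                                           max_relative_deviation=dev))
    return entries


def gamma_robustness_refit(
    topology: NetworkTopology | None = None,
    params: KineticParameters | None = None,
    schedule: TriggerSchedule | None = None,
    factor: float = 2.0,
    restarts: int = 1,
    seed: int = 0,
    continuation: bool = True,
    policy: ThresholdPolicy | None = None,
) -> list[RobustnessEntry]:
    """Robustness of the identified minimum to the affinity-ratio choice.

    For each dimer and each direction, the affinity is scaled, the six
    decoupled equations are re-identified on the reference synthetic data
    (starting from the identified minimum, i.e. local tracking), and the
    re-fitted model is re-simulated and classified.  This probes whether a
    nearby local minimum with the same qualitative behaviour exists under
    the perturbed affinities, which is the meaningful robustness question
    for a local identification method; contrast with
    :func:`gamma_robustness`, which re-simulates with frozen parameters.
    """
    from .estimation import ParameterBounds, fit_all, pack_parameters
    from .synth import generate_truth

    config = SyntheticConfig(topology=topology, params=params,
                             schedule=schedule or TriggerSchedule(), sigma=0.0)
    topology, params, schedule = config.topology, config.params, config.schedule
    policy = policy or ThresholdPolicy()
    truth = generate_truth(config)
    bounds, _ = ParameterBounds().widen_to_include(params)

    def continuation_init(dimer_name: str, f: float) -> dict[str, np.ndarray]:
        # a scaled affinity multiplies that dimer's concentration by f at
        # given monomers; scaling its Km slots by f preserves every
        # Michaelis-Menten fraction, so the previous minimum maps to an
        # equivalent starting point of the perturbed problem
        compensated = params.copy()
        for g in GENES:
            compensated.km_act[g] = tuple(
                km * f if d == dimer_name else km
                for km, d in zip(compensated.km_act[g], topology.activators[g])
            )
            compensated.km_rep[g] = tuple(
                km * f if d == dimer_name else km
                for km, d in zip(compensated.km_rep[g], topology.repressors[g])
            )
        return {g: pack_parameters(compensated, g, topology) for g in GENES}

    entries: list[RobustnessEntry] = []
    for spec_d in topology.dimers:
        for f in (factor, 1.0 / factor):
            perturbed = topology.scaled_gamma(spec_d.name, f)
            init = (continuation_init(spec_d.name, f) if continuation
                    else {g: pack_parameters(params, g, topology) for g in GENES})
            refit, _ = fit_all(truth, perturbed, bounds=bounds, schedule=schedule,
                               initial=init, restarts=restarts, seed=seed)
            result = run_mutant(MutantSpec(kind="wild_type"), perturbed, refit,
                                schedule, policy)
            unchanged = all(
                result.calls[w].label == WILD_TYPE_CALLS[w] for w in WHORLS
            )
            entries.append(RobustnessEntry(dimer=spec_d.name, factor=f,
                                           calls_unchanged=unchanged,
                                           max_relative_deviation=float("nan")))
    return entries


def literature_concordance(
    results: Mapping[str, MutantResult] | None = None,
    topology: NetworkTopology | None = None,
    params: KineticParameters | None = None,
    schedule: TriggerSchedule | None = None,
    policy: ThresholdPolicy | None = None,
) -> tuple[int, int, dict[str, tuple[str, ...]]]:
    """Compare the five literature mutants with their known phenotypes.

    Returns (#full matches, #partial matches) plus the simulated per-whorl
    calls.  A full match reproduces all four whorls; a partial match some
    but not all.
    """
    if results is None:
        specs = {
            "ap3-ko": MutantSpec(kind="knockout", target="AP3"),
            "pi-ko": MutantSpec(kind="knockout", target="PI"),
            "ap3-oe": MutantSpec(kind="ectopic", target="AP3"),
            "ag-oe": MutantSpec(kind="ectopic", target="AG"),
            "ag-ko": MutantSpec(kind="knockout", target="AG"),
        }
        results = {
            name: run_mutant(spec, topology, params, schedule, policy)
            for name, spec in specs.items()
        }
    n_full = n_partial = 0
    simulated: dict[str, tuple[str, ...]] = {}
    for name, expected in LITERATURE_MUTANTS.items():
        calls = tuple(results[name].calls[w].label for w in WHORLS)
        simulated[name] = calls
        n_match = sum(a == b for a, b in zip(calls, expected))
        if n_match == 4:
            n_full += 1
        elif n_match > 0:
            n_partial += 1
    return n_full, n_partial, simulated
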