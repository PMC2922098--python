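"""Gene/dimer network data model and the full coupled monomer+dimer ODE system.

The network comprises the six MADS-box floral organ identity proteins of
*Arabidopsis thaliana* — AP1 (A function), AP3 and PI (B), AG (C), SHP (D)
and SEP (E) — together with the seven protein dimers they form.  Dimers are
the DNA-binding species: transcription of each gene is activated by a set
of dimers (Michaelis–Menten kinetics, OR-logic) and only proceeds while all
repressing dimers are absent from their sites.  Two timed, whorl-specific
trigger inputs (standing in for LFY/UFO and WUS/LFY activity) fire between
day 1 and day 2 of meristem development and push the network into the four
whorl-specific expression states that encode sepal, petal, stamen and
carpel identity.

Units: concentrations in nM, time in days, rates in nM/day or 1/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GENES",
    "GENE_INDEX",
    "DimerSpec",
    "NetworkTopology",
    "KineticParameters",
    "TriggerSchedule",
    "FullState",
    "Trajectory",
    "build_default_topology",
    "production_rate",
    "trigger_input",
    "coupled_rhs",
    "simulate_full",
]

#: Gene names in canonical order; position i holds the protein x_{i+1}.
GENES: tuple[str, ...] = ("AP1", "AP3", "PI", "AG", "SHP", "SEP")

#: 1-based index of each gene (AP1 -> 1 ... SEP -> 6).
GENE_INDEX: dict[str, int] = {g: i + 1 for i, g in enumerate(GENES)}

#: Default dissociation rate, 1/min expressed in 1/day.  Dimerization is
#: then firmly in the fast regime the quasi-steady-state reduction assumes;
#: only the ratio gamma = kon/koff matters for the reduced dynamics.
DEFAULT_KOFF = 1440.0


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    for g in (a, b):
        if g not in GENE_INDEX:
            raise ValueError(f"unknown gene {g!r}")
    return (a, b) if GENE_INDEX[a] <= GENE_INDEX[b] else (b, a)


@dataclass(frozen=True)
class DimerSpec:
    """One dimer species: an unordered pair of partners and its affinity.

    ``gamma`` is the association/dissociation ratio Kon/Koff in 1/nM; it is
    the only dimer parameter entering the reduced (quasi-steady-state)
    model.  ``koff`` (1/day) sets the absolute timescale of the full model;
    ``kon = gamma * koff``.
    """

    partners: tuple[str, str]
    gamma: float
    koff: float = DEFAULT_KOFF

    def __post_init__(self) -> None:
        object.__setattr__(self, "partners", _canonical_pair(*self.partners))
        if not self.gamma >= 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not self.koff > 0:
            raise ValueError(f"koff must be > 0, got {self.koff}")

    @property
    def kon(self) -> float:
        """Association rate in 1/(nM day)."""
        return self.gamma * self.koff

    @property
    def is_homodimer(self) -> bool:
        return self.partners[0] == self.partners[1]

    @property
    def name(self) -> str:
        return f"[{self.partners[0]} {self.partners[1]}]"

    def contains(self, gene: str) -> bool:
        return gene in self.partners

    def stoichiometry(self, gene: str) -> int:
        """Monomers of ``gene`` consumed per dimer formed (0, 1 or 2)."""
        return self.partners.count(gene)


def dimer_name(a: str, b: str) -> str:
    pa, pb = _canonical_pair(a, b)
    return f"[{pa} {pb}]"


#: Dimer species of the default network.
DEFAULT_DIMER_NAMES: tuple[str, ...] = (
    "[AP1 SEP]",
    "[AG AG]",
    "[AG SEP]",
    "[AP3 PI]",
    "[AP1 AP1]",
    "[SEP SEP]",
    "[SHP SEP]",
)

#: Calibrated assignment of the fixed affinity ratios (1/nM) to dimers.
#: The value multiset {1, 0.1, 0.1, 0.01, 0.01, 5e-3, 5e-3} is literature-
#: derived; the assignment to species is the package's calibration choice
#: (see docs/methods.md) and is explicit in every saved run manifest.
DEFAULT_GAMMA: dict[str, float] = {
    "[AG AG]": 1.0,
    "[AG SEP]": 1e-1,
    "[SEP SEP]": 1e-1,
    "[AP3 PI]": 1e-2,
    "[SHP SEP]": 1e-2,
    "[AP1 SEP]": 5e-3,
    "[AP1 AP1]": 5e-3,
}

#: Activating dimers per gene, in slot order: slot k of gene i carries the
#: identified pair (beta_{i,k}, Km_{i,k}).  AP3 and PI place their
#: autoregulatory [AP3 PI] slot first — it carries the large beta that
#: latches B-function expression after the trigger; the remaining genes
#: keep the conventional wiring-table order.
DEFAULT_ACTIVATORS: dict[str, tuple[str, ...]] = {
    "AP1": ("[AP1 SEP]",),
    "AP3": ("[AP3 PI]", "[AP1 SEP]", "[AG SEP]"),
    "PI": ("[AP3 PI]", "[AP1 SEP]", "[AG SEP]"),
    "AG": ("[AG SEP]", "[AG AG]"),
    "SHP": ("[AG SEP]",),
    "SEP": ("[AG SEP]", "[AP1 SEP]", "[SEP SEP]"),
}

#: Repressing dimers per gene (empty tuple: no repressor).
DEFAULT_REPRESSORS: dict[str, tuple[str, ...]] = {
    "AP1": ("[AG AG]",),
    "AP3": (),
    "PI": (),
    "AG": ("[AP1 AP1]",),
    "SHP": ("[AP3 PI]",),
    "SEP": (),
}


@dataclass(frozen=True)
class NetworkTopology:
    """The 6-gene, 7-dimer regulatory wiring.

    ``activators``/``repressors`` list dimer *names* per gene; activator
    order defines the parameter slots of :class:`KineticParameters`.
    """

    genes: tuple[str, ...] = GENES
    dimers: tuple[DimerSpec, ...] = ()
    activators: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    repressors: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [d.name for d in self.dimers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimer species")
        known = set(names)
        for table in (self.activators, self.repressors):
            for gene, dims in table.items():
                if gene not in GENE_INDEX:
                    raise ValueError(f"unknown gene {gene!r}")
                missing = [d for d in dims if d not in known]
                if missing:
                    raise ValueError(f"unlisted dimer(s) {missing} wired to {gene}")

    # -- lookups ---------------------------------------------------------
    @property
    def dimer_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimers)

    def dimer(self, name: str) -> DimerSpec:
        for d in self.dimers:
            if d.name == name:
                return d
        raise KeyError(name)

    def gamma(self, name: str) -> float:
        return self.dimer(name).gamma

    def dimers_containing(self, gene: str) -> tuple[DimerSpec, ...]:
        return tuple(d for d in self.dimers if d.contains(gene))

    @property
    def n_states(self) -> int:
        """State variables of the full coupled model (monomers + dimers)."""
        return len(self.genes) + len(self.dimers)

    # -- structural audit ------------------------------------------------
    def n_beta(self) -> int:
        return sum(len(v) for v in self.activators.values())

    def n_km(self) -> int:
        return self.n_beta() + sum(len(v) for v in self.repressors.values())

    def total_parameter_count(self) -> int:
        """Parameters of the full model: beta, Km, decay, 2 triggers, and
        one (Kon, Koff) pair per dimer."""
        return self.n_beta() + self.n_km() + len(self.genes) + 2 + 2 * len(self.dimers)

    def free_parameter_count(self) -> int:
        """Parameters left free in the reduced model once the affinity
        ratios and Koff are fixed."""
        return self.n_beta() + self.n_km() + len(self.genes) + 2

    # -- perturbations ---------------------------------------------------
    def with_gamma(self, updates: Mapping[str, float]) -> "NetworkTopology":
        """Return a copy with some dimer affinities replaced (e.g. set to
        zero for a dimer-removal mutant)."""
        new = tuple(
            replace(d, gamma=updates.get(d.name, d.gamma)) for d in self.dimers
        )
        return replace(self, dimers=new)

    def scaled_gamma(self, name: str, factor: float) -> "NetworkTopology":
        return self.with_gamma({name: self.gamma(name) * factor})


def build_default_topology(
    gamma: Mapping[str, float] | None = None,
    koff: float = DEFAULT_KOFF,
    activators: Mapping[str, Sequence[str]] | None = None,
    repressors: Mapping[str, Sequence[str]] | None = None,
) -> NetworkTopology:
    """Build the 6-gene, 7-dimer floral network with its default wiring.

    Parameters default to the packaged calibration: affinity ratios from
    :data:`DEFAULT_GAMMA`, activator slot order from
    :data:`DEFAULT_ACTIVATORS`.  Pass ``gamma`` to override individual
    affinities (missing names keep their default).
    """
    gmap = dict(DEFAULT_GAMMA)
    if gamma:
        unknown = set(gamma) - set(DEFAULT_DIMER_NAMES)
        if unknown:
            raise ValueError(f"unknown dimer name(s): {sorted(unknown)}")
        gmap.update(gamma)
    dimers = tuple(
        DimerSpec(partners=tuple(n.strip("[]").split()), gamma=gmap[n], koff=koff)
        for n in DEFAULT_DIMER_NAMES
    )
    act = {g: tuple(v) for g, v in (activators or DEFAULT_ACTIVATORS).items()}
    rep = {g: tuple(v) for g, v in (repressors or DEFAULT_REPRESSORS).items()}
    return NetworkTopology(genes=GENES, dimers=dimers, activators=act, repressors=rep)


@dataclass
class KineticParameters:
    """Kinetic parameters of the reduced model, slot-aligned with a topology.

    ``beta[g][k]`` (nM/day) and ``km_act[g][k]`` (nM) belong to the k-th
    activating dimer of gene ``g``; ``km_rep[g][r]`` to its r-th repressor;
    ``dc[g]`` (1/day) is first-order decay; ``p2_magnitude``/``p4_magnitude``
    (nM/day) are the AP3 and AG trigger rates.
    """

    beta: dict[str, tuple[float, ...]]
    km_act: dict[str, tuple[float, ...]]
    km_rep: dict[str, tuple[float, ...]]
    dc: dict[str, float]
    p2_magnitude: float
    p4_magnitude: float

    def validate(self, topology: NetworkTopology) -> None:
        for g in topology.genes:
            if len(self.beta[g]) != len(topology.activators[g]):
                raise ValueError(f"beta slot count mismatch for {g}")
            if len(self.km_act[g]) != len(topology.activators[g]):
                raise ValueError(f"km_act slot count mismatch for {g}")
            if len(self.km_rep[g]) != len(topology.repressors[g]):
                raise ValueError(f"km_rep slot count mismatch for {g}")
        values = list(self.dc.values()) + [self.p2_magnitude, self.p4_magnitude]
        for g in topology.genes:
            values += list(self.beta[g]) + list(self.km_act[g]) + list(self.km_rep[g])
        if not all(v > 0 for v in values):
            raise ValueError("all kinetic parameters must be strictly positive")

    def free_parameter_count(self) -> int:
        n = 2 + len(self.dc)
        for g in self.beta:
            n += len(self.beta[g]) + len(self.km_act[g]) + len(self.km_rep[g])
        return n

    def copy(self) -> "KineticParameters":
        return KineticParameters(
            beta={g: tuple(v) for g, v in self.beta.items()},
            km_act={g: tuple(v) for g, v in self.km_act.items()},
            km_rep={g: tuple(v) for g, v in self.km_rep.items()},
            dc=dict(self.dc),
            p2_magnitude=self.p2_magnitude,
            p4_magnitude=self.p4_magnitude,
        )


@dataclass(frozen=True)
class TriggerSchedule:
    """Timing and spatial domain of the two trigger inputs.

    The AP3 trigger (p2) fires in the future petal and stamen whorls, the
    AG trigger (p4) in the stamen and carpel whorls, both on the half-open
    window [t_on, t_off) — by default the second day of development.
    """

    t_on: float = 1.0
    t_off: float = 2.0
    p2_whorls: frozenset[int] = frozenset({2, 3})
    p4_whorls: frozenset[int] = frozenset({3, 4})

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError("t_on must be < t_off")
        if not (set(self.p2_whorls) <= {1, 2, 3, 4} and set(self.p4_whorls) <= {1, 2, 3, 4}):
            raise ValueError("whorl ids must be in {1, 2, 3, 4}")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.t_on, self.t_off)


@dataclass
class FullState:
    """State of the coupled model: 6 monomer + 7 dimer concentrations (nM)."""

    monomers: np.ndarray
    dimers: np.ndarray

    def __post_init__(self) -> None:
        self.monomers = np.asarray(self.monomers, dtype=float)
        self.dimers = np.asarray(self.dimers, dtype=float)
        if self.monomers.shape != (6,) or self.dimers.shape != (7,):
            raise ValueError("expected 6 monomer and 7 dimer concentrations")
        if (self.monomers < 0).any() or (self.dimers < 0).any():
            raise ValueError("concentrations must be non-negative")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.monomers, self.dimers])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "FullState":
        y = np.asarray(y, dtype=float)
        return cls(monomers=y[:6], dimers=y[6:13])


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def production_rate(
    gene: str,
    dimer_concentrations: Mapping[str, float],
    params: KineticParameters,
    topology: NetworkTopology,
) -> float:
    """Transcriptional production rate of ``gene`` in nM/day.

    Sum of Michaelis–Menten activation terms over the gene's activating
    dimers, multiplied by an occupancy-free factor Km/(Km+R) for every
    repressing dimer: transcription needs at least one occupied activation
    site and all repression sites empty.
    """
    if gene not in topology.activators:
        raise KeyError(f"unknown gene {gene!r}")
    total = 0.0
    for b, km, name in zip(
        params.beta[gene], params.km_act[gene], topology.activators[gene]
    ):
        try:
            a = dimer_concentrations[name]
        except KeyError:
            raise KeyError(f"missing concentration for dimer {name}") from None
        if a < 0:
            raise ValueError(f"negative concentration for {name}")
        total += b * a / (km + a)
    for km, name in zip(params.km_rep[gene], topology.repressors[gene]):
        try:
            r = dimer_concentrations[name]
        except KeyError:
            raise KeyError(f"missing concentration for dimer {name}") from None
        if r < 0:
            raise ValueError(f"negative concentration for {name}")
        total *= km / (km + r)
    return total


def trigger_input(
    gene: str,
    t: float,
    whorl: int,
    schedule: TriggerSchedule,
    params: KineticParameters,
) -> float:
    """Trigger production rate (nM/day) for ``gene`` at time ``t`` in ``whorl``.

    Nonzero only for AP3 (p2) and AG (p4) inside the trigger window and in
    the whorls the schedule assigns to each trigger.
    """
    if not schedule.t_on <= t < schedule.t_off:
        return 0.0
    if gene == "AP3" and whorl in schedule.p2_whorls:
        return params.p2_magnitude
    if gene == "AG" and whorl in schedule.p4_whorls:
        return params.p4_magnitude
    return 0.0


def _production_vector(
    x: np.ndarray,
    dimer_conc: Mapping[str, float],
    t: float,
    whorl: int,
    topology: NetworkTopology,
    params: KineticParameters,
    schedule: TriggerSchedule,
) -> np.ndarray:
    """production + trigger - decay for each monomer (no dimer fluxes)."""
    g = np.empty(6)
    for i, gene in enumerate(topology.genes):
        g[i] = (
            production_rate(gene, dimer_conc, params, topology)
            + trigger_input(gene, t, whorl, schedule, params)
            - params.dc[gene] * x[i]
        )
    return g


def coupled_rhs(
    t: float,
    state: np.ndarray | FullState,
    whorl: int,
    topology: NetworkTopology,
    params: KineticParameters,
    schedule: TriggerSchedule,
) -> np.ndarray:
    """Right-hand side of the full 13-dimensional monomer+dimer system.

    Dimer dynamics: kon*x_i*x_j - koff*[x_i x_j] (kon*x_i^2 for
    homodimers).  Monomer dynamics: production + trigger - decay minus the
    net dimerization flux, counted twice for homodimers.
    """
    if isinstance(state, FullState):
        y = state.to_vector()
    else:
        y = np.asarray(state, dtype=float)
        if (y < 0).any():
            raise ValueError("negative concentrations rejected")
    x, d = y[:6], y[6:13]
    dimer_conc = dict(zip(topology.dimer_names, d))
    dydt = np.zeros(13)
    dydt[:6] = _production_vector(x, dimer_conc, t, whorl, topology, params, schedule)
    for j, spec in enumerate(topology.dimers):
        ia = GENE_INDEX[spec.partners[0]] - 1
        ib = GENE_INDEX[spec.partners[1]] - 1
        flux = spec.kon * x[ia] * x[ib] - spec.koff * d[j]
        dydt[6 + j] = flux
        dydt[ia] -= flux
        dydt[ib] -= flux  # homodimers: both terms hit the same gene (s = 2)
    return dydt


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-resolved concentrations in one whorl.

    ``monomers`` has shape (T, 6) with columns in :data:`GENES` order;
    ``dimers`` (T, 7) follows ``topology.dimer_names``.  For reduced-model
    output the dimer block holds the quasi-steady-state values.
    """

    whorl: int
    times: np.ndarray
    monomers: np.ndarray
    dimers: np.ndarray
    topology: NetworkTopology

    def gene(self, name: str, representation: str = "monomer") -> np.ndarray:
        i = GENE_INDEX[name] - 1
        if representation == "monomer":
            return self.monomers[:, i]
        if representation == "total":
            return self.totals()[:, i]
        if representation == "bound":
            return self.totals()[:, i] - self.monomers[:, i]
        raise ValueError(f"unknown representation {representation!r}")

    def dimer(self, name: str) -> np.ndarray:
        return self.dimers[:, self.topology.dimer_names.index(name)]

    def totals(self) -> np.ndarray:
        """Total (monomer + dimer-bound) concentration per gene, (T, 6)."""
        tot = self.monomers.copy()
        for j, spec in enumerate(self.topology.dimers):
            for partner in set(spec.partners):
                i = GENE_INDEX[partner] - 1
                tot[:, i] += spec.stoichiometry(partner) * self.dimers[:, j]
        return tot

    def at_time(self, t: float) -> int:
        """Index of the stored time closest to ``t``."""
        return int(np.argmin(np.abs(self.times - t)))


def _integrate_piecewise(rhs, t_span, y0, t_eval, edges, solver_options):
    """LSODA integration restarted at trigger-window edges."""
    opts = {"rtol": 1e-6, "atol": 1e-3, "method": "LSODA"}
    opts.update(solver_options or {})
    method = opts.pop("method")
    t0, t1 = t_span
    breaks = [t0] + [e for e in sorted(edges) if t0 < e < t1] + [t1]
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        # evaluate the open-right window: triggers are right-continuous
        sub_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        sub_eval = np.unique(np.concatenate([[a], sub_eval, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method=method, t_eval=sub_eval, **opts)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed near t = {sol.t[-1] if len(sol.t) else a:.4f} d: "
                f"{sol.message}"
            )
        keep = np.isin(sol.t, t_eval) if len(ts) == 0 else (
            np.isin(sol.t, t_eval) & (sol.t > a)
        )
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1]
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    return t, Y.T


def simulate_full(
    initial: FullState | np.ndarray,
    t_span: tuple[float, float],
    whorl: int,
    topology: NetworkTopology,
    params: KineticParameters,
    schedule: TriggerSchedule | None = None,
    t_eval: Iterable[float] | None = None,
    solver_options: dict | None = None,
) -> Trajectory:
    """Integrate the full coupled 13-state system in one whorl.

    Returns monomer and dimer trajectories at ``t_eval`` (default: 0.01-day
    grid over ``t_span``).  Output concentrations are clipped at zero for
    reporting; the integration itself is restarted at the trigger edges so
    the day-scale discontinuities never sit inside a solver step.
    """
    schedule = schedule or TriggerSchedule()
    y0 = initial.to_vector() if isinstance(initial, FullState) else np.asarray(initial, float)
    if y0.shape != (13,):
        raise ValueError("full-model initial state must have 13 entries")
    if (y0 < 0).any():
        raise ValueError("negative concentrations rejected")
    if t_eval is None:
        t_eval = np.arange(t_span[0], t_span[1] + 1e-9, 0.01)
    t_eval = np.asarray(list(t_eval), dtype=float)

    def rhs(t, y):
        return coupled_rhs(t, np.maximum(y, 0.0), whorl, topology, params, schedule)

    t, Y = _integrate_piecewise(rhs, t_span, y0, t_eval, schedule.edges, solver_options)
    Y = np.maximum(Y, 0.0)
    return Trajectory(whorl=whorl, times=t, monomers=Y[:, :6], dimers=Y[:, 6:13],
                      topology=topology)
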