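"""Decoupling-based parameter identification.

The reduced model has the property that no kinetic parameter appears in
more than one gene's equation, so the 37-parameter problem splits into six
independent scalar problems.  For the target gene, every other monomer
concentration (and its derivative, which enters through the mass-matrix
coupling) is replaced by a piecewise-linear interpolation of the data;
the target equation is then integrated per whorl from the day-0 data
point, and its parameters are found by bounded nonlinear least squares on
the residuals model - data over days 1..5 and all four whorls.

Data enter as *monomer* concentrations, obtained from the measured totals
by inverting the quasi-steady-state mass balance at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .network import (
    GENE_INDEX,
    GENES,
    KineticParameters,
    NetworkTopology,
    TriggerSchedule,
)
from .qss import monomers_from_totals, qss_dimer
from .transform import WHORLS, ConcentrationGrid

__all__ = [
    "ParameterBounds",
    "EstimationProblem",
    "FitResult",
    "monomer_data",
    "interpolate_fixed",
    "initialize_km",
    "gradient_match_initial",
    "fit_equation",
    "fit_all",
    "parameter_names",
    "pack_parameters",
]

#: minutes-to-days conversion for literature rate ranges
PER_MIN_TO_PER_DAY = 1440.0


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds per parameter class (all in nM/day, nM, 1/day).

    Literature ranges are quoted per minute (beta in [1, 50] nM/min, decay
    in [1e-3, 1e-1] 1/min) and converted by the factor 1440; Km spans
    [10, 1e3] nM; the trigger magnitudes are positive and unbounded above.
    """

    beta: tuple[float, float] = (1.0 * PER_MIN_TO_PER_DAY, 50.0 * PER_MIN_TO_PER_DAY)
    km: tuple[float, float] = (10.0, 1.0e3)
    dc: tuple[float, float] = (1.0e-3 * PER_MIN_TO_PER_DAY, 1.0e-1 * PER_MIN_TO_PER_DAY)
    trigger: tuple[float, float] = (1.0e-6, np.inf)

    def __post_init__(self) -> None:
        for lo, hi in (self.beta, self.km, self.dc, self.trigger):
            if not lo < hi:
                raise ValueError("each bound must satisfy lower < upper")

    def for_class(self, cls: str) -> tuple[float, float]:
        return getattr(self, cls)

    def widen_to_include(
        self, params: KineticParameters, margin: float = 1.05
    ) -> tuple["ParameterBounds", list[str]]:
        """Expand class ranges so every value of ``params`` fits inside.

        Returns the widened bounds and the class names that had to move —
        the identified reference set itself sits outside the nominal
        literature ranges for a handful of entries.
        """
        betas = [v for vs in params.beta.values() for v in vs]
        kms = [v for vs in params.km_act.values() for v in vs]
        kms += [v for vs in params.km_rep.values() for v in vs]
        dcs = list(params.dc.values())
        widened: list[str] = []

        def expand(cls: str, values: list[float]) -> tuple[float, float]:
            lo, hi = self.for_class(cls)
            new_lo = min(lo, min(values) / margin)
            new_hi = max(hi, max(values) * margin)
            if (new_lo, new_hi) != (lo, hi):
                widened.append(cls)
            return (new_lo, new_hi)

        return (
            ParameterBounds(
                beta=expand("beta", betas),
                km=expand("km", kms),
                dc=expand("dc", dcs),
                trigger=self.trigger,
            ),
            widened,
        )


def parameter_names(gene: str, topology: NetworkTopology) -> list[str]:
    """Free parameters of one decoupled equation, in packing order."""
    names = [f"beta:{d}" for d in topology.activators[gene]]
    names += [f"km_act:{d}" for d in topology.activators[gene]]
    names += [f"km_rep:{d}" for d in topology.repressors[gene]]
    names.append("dc")
    if gene == "AP3":
        names.append("p2")
    elif gene == "AG":
        names.append("p4")
    return names


def pack_parameters(
    params: KineticParameters, gene: str, topology: NetworkTopology
) -> np.ndarray:
    """Pack one gene's kinetic parameters into the fit vector layout."""
    theta = list(params.beta[gene]) + list(params.km_act[gene]) \
        + list(params.km_rep[gene]) + [params.dc[gene]]
    if gene == "AP3":
        theta.append(params.p2_magnitude)
    elif gene == "AG":
        theta.append(params.p4_magnitude)
    return np.asarray(theta, dtype=float)


def _bounds_vectors(
    gene: str, topology: NetworkTopology, bounds: ParameterBounds
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in parameter_names(gene, topology):
        cls = {"beta": "beta", "km_a": "km", "km_r": "km", "dc": "dc",
               "p2": "trigger", "p4": "trigger"}[name[:4]]
        b = bounds.for_class(cls)
        lo.append(b[0])
        hi.append(b[1])
    return np.asarray(lo), np.asarray(hi)


def monomer_data(totals: ConcentrationGrid, topology: NetworkTopology,
                 tol: float = 1e-10) -> ConcentrationGrid:
    """Invert the mass balance at every (whorl, day) grid point."""
    values = np.empty_like(totals.values)
    for wi in range(len(WHORLS)):
        for di in range(len(totals.days)):
            try:
                values[:, wi, di] = monomers_from_totals(
                    totals.values[:, wi, di], topology, tol=tol
                )
            except RuntimeError as err:
                raise RuntimeError(
                    f"inversion failed at whorl {wi + 1}, day {totals.days[di]}: {err}"
                ) from err
    return ConcentrationGrid(values=values, days=totals.days)


class interpolate_fixed:
    """Piecewise-linear interpolant with forward-difference derivative.

    The value is linear on each day interval; the derivative is the
    forward difference, right-continuous at the knots, with the last
    interval's slope extended beyond the final knot.
    """

    def __init__(self, days: Sequence[float], values: Sequence[float]):
        self.days = np.asarray(days, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.days) < 2:
            raise ValueError("need at least two time points to interpolate")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        self.slopes = np.diff(self.values) / np.diff(self.days)

    def _segment(self, t: float) -> int:
        return int(np.clip(np.searchsorted(self.days, t, side="right") - 1,
                           0, len(self.slopes) - 1))

    def __call__(self, t: float) -> float:
        j = self._segment(t)
        return float(self.values[j] + (t - self.days[j]) * self.slopes[j])

    def derivative(self, t: float) -> float:
        return float(self.slopes[self._segment(t)])


@dataclass
class EstimationProblem:
    """One decoupled scalar identification problem.

    ``data`` is the monomer grid for *all* genes; the target gene's values
    are the fit targets, the others provide the interpolated fixed inputs.
    """

    gene: str
    data: ConcentrationGrid
    topology: NetworkTopology
    schedule: TriggerSchedule = field(default_factory=TriggerSchedule)
    bounds: ParameterBounds = field(default_factory=ParameterBounds)

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}")

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.data.days, dtype=float)

    @property
    def n_parameters(self) -> int:
        return len(parameter_names(self.gene, self.topology))


@dataclass
class FitResult:
    """Outcome of one decoupled fit (or an assembled set of six)."""

    gene: str
    parameters: dict[str, float]
    objective: float
    at_bound: dict[str, str]  # parameter -> "lower" | "upper"
    success: bool
    message: str
    n_evaluations: int
    widened_bound_classes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Decoupled right-hand side (vectorized over the four whorls)
# ---------------------------------------------------------------------------

class _DecoupledModel:
    """Scalar ODE of one gene with all other genes supplied by data.

    Integrates the four whorls simultaneously (they share parameters but
    have different fixed inputs), one component per whorl.
    """

    def __init__(self, problem: EstimationProblem):
        self.problem = problem
        topo = problem.topology
        gene = problem.gene
        self.gi = GENE_INDEX[gene] - 1
        self.days = problem.days
        # V[w, g, d] data values; S[w, g, d] forward-difference slopes
        self.V = np.transpose(problem.data.values, (1, 0, 2))
        self.S = np.diff(self.V, axis=2) / np.diff(self.days)
        # regulation structure: (dimer gamma, partner index or None=self)
        def factors(dimer_name: str) -> tuple[float, int, int]:
            spec = topo.dimer(dimer_name)
            ia = GENE_INDEX[spec.partners[0]] - 1
            ib = GENE_INDEX[spec.partners[1]] - 1
            return spec.gamma, ia, ib

        self.act = [factors(d) for d in topo.activators[gene]]
        self.rep = [factors(d) for d in topo.repressors[gene]]
        # mass-matrix row: heterodimer partners and homodimer gamma
        self.het_partners: list[tuple[float, int]] = []
        self.gamma_homo = 0.0
        for spec in topo.dimers_containing(gene):
            if spec.is_homodimer:
                self.gamma_homo = spec.gamma
            else:
                other = spec.partners[0] if spec.partners[1] == gene else spec.partners[1]
                self.het_partners.append((spec.gamma, GENE_INDEX[other] - 1))
        self.trigger_whorls = np.zeros(4)
        sched = problem.schedule
        if gene == "AP3":
            self.trigger_whorls = np.array([float(w in sched.p2_whorls) for w in WHORLS])
        elif gene == "AG":
            self.trigger_whorls = np.array([float(w in sched.p4_whorls) for w in WHORLS])

    def _data_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        j = int(np.clip(np.searchsorted(self.days, t, side="right") - 1,
                        0, self.S.shape[2] - 1))
        xk = self.V[:, :, j] + (t - self.days[j]) * self.S[:, :, j]
        return xk, self.S[:, :, j]

    def rhs(self, t: float, x: np.ndarray, theta: np.ndarray,
            trigger_on: bool) -> np.ndarray:
        """dx/dt for the 4 whorls; theta is the packed parameter vector."""
        x = np.maximum(x, 0.0)
        xk, dxk = self._data_at(t)
        gene_i = self.gi
        n_act = len(self.act)
        n_rep = len(self.rep)
        beta = theta[:n_act]
        km_a = theta[n_act:2 * n_act]
        km_r = theta[2 * n_act:2 * n_act + n_rep]
        dc = theta[2 * n_act + n_rep]
        trig = theta[-1] if len(theta) > 2 * n_act + n_rep + 1 else 0.0

        def dimer_conc(gamma: float, ia: int, ib: int) -> np.ndarray:
            fa = x if ia == gene_i else xk[:, ia]
            fb = x if ib == gene_i else xk[:, ib]
            return gamma * fa * fb

        prod = np.zeros(4)
        for k, (gamma, ia, ib) in enumerate(self.act):
            a = dimer_conc(gamma, ia, ib)
            prod += beta[k] * a / (km_a[k] + a)
        for r, (gamma, ia, ib) in enumerate(self.rep):
            rconc = dimer_conc(gamma, ia, ib)
            prod *= km_r[r] / (km_r[r] + rconc)
        g = prod - dc * x
        if trigger_on:
            g = g + trig * self.trigger_whorls
        # mass-matrix row: M_ii * dx_i + sum_k gamma_ik x_i dx_k = g
        m_ii = 1.0 + 4.0 * self.gamma_homo * x
        coupling = np.zeros(4)
        for gamma, k in self.het_partners:
            m_ii += gamma * xk[:, k]
            coupling += gamma * x * dxk[:, k]
        return (g - coupling) / m_ii

    def integrate(self, theta: np.ndarray) -> np.ndarray:
        """Model values at the data days, shape (4 whorls, D days)."""
        days = self.days
        sched = self.problem.schedule
        knots = np.unique(np.concatenate([days, np.asarray(sched.edges)]))
        knots = knots[(knots >= days[0]) & (knots <= days[-1])]
        x = self.V[:, self.gi, 0].copy()
        out = np.empty((4, len(days)))
        out[:, 0] = x
        for a, b in zip(knots[:-1], knots[1:]):
            mid = 0.5 * (a + b)
            trigger_on = sched.t_on <= mid < sched.t_off
            sol = solve_ivp(
                self.rhs, (a, b), x, args=(theta, trigger_on),
                method="LSODA", rtol=1e-7, atol=1e-4,
            )
            if not sol.success:
                raise RuntimeError(f"decoupled integration failed at t={a}: {sol.message}")
            x = np.maximum(sol.y[:, -1], 0.0)
            hit = np.nonzero(np.isclose(days, b))[0]
            if hit.size:
                out[:, hit[0]] = x
        return out

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        model = self.integrate(theta)
        data = self.V[:, self.gi, :]
        return (model[:, 1:] - data[:, 1:]).ravel()  # day 0 is the IC


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_km(
    gene: str,
    typical_monomers: Mapping[str, float],
    topology: NetworkTopology,
    bounds: ParameterBounds,
) -> list[float]:
    """Km starting values: the typical concentration of each slot's dimer.

    At x = Km the Michaelis-Menten fraction has its maximal parameter
    sensitivity (|d/dKm| = 1/(4 Km)), so starting every Km at the typical
    level of its governing dimer signal puts the search in the responsive
    regime.  Values are clipped to the bounds.
    """
    lo, hi = bounds.km
    inits = []
    for name in list(topology.activators[gene]) + list(topology.repressors[gene]):
        spec = topology.dimer(name)
        a, b = spec.partners
        signal = qss_dimer(typical_monomers[a], typical_monomers[b], spec.gamma)
        inits.append(float(np.clip(signal, lo, hi)))
    return inits


def gradient_match_initial(
    problem: EstimationProblem, theta0: np.ndarray | None = None
) -> np.ndarray:
    """Derivative-collocation pre-fit used as the default starting point.

    Matches the decoupled right-hand side to the forward-difference
    derivative of the target gene's data at the day-interval midpoints —
    an algebraic regression that needs no ODE solves and lands the
    subsequent trajectory fit near a data-consistent basin.
    """
    model = _DecoupledModel(problem)
    lo, hi = _bounds_vectors(problem.gene, problem.topology, problem.bounds)
    if theta0 is None:
        theta0 = _default_initial(problem)
    theta0 = np.clip(theta0, lo, np.where(np.isfinite(hi), hi, theta0))
    days = problem.days
    mids = 0.5 * (days[:-1] + days[1:])
    sched = problem.schedule

    def resid(theta: np.ndarray) -> np.ndarray:
        parts = []
        for k, tm in enumerate(mids):
            xk, _ = model._data_at(tm)
            trig = sched.t_on <= tm < sched.t_off
            parts.append(model.rhs(tm, xk[:, model.gi], theta, trig)
                         - model.S[:, model.gi, k])
        return np.concatenate(parts)

    res = least_squares(resid, theta0, bounds=(lo, hi), x_scale="jac", max_nfev=300)
    return res.x


def _default_initial(problem: EstimationProblem, dc0: float | None = None) -> np.ndarray:
    """Data-informed starting point.

    Km slots start at the typical dimer signal (maximal Michaelis-Menten
    sensitivity); decay starts at the geometric mid-range (or ``dc0``);
    beta slots start on the steady-state balance beta ~ dc * x_on at the
    gene's observed on-level, split over the activator slots.
    """
    data = problem.data
    day_sel = [i for i, d in enumerate(data.days) if d >= 2]
    typical = {
        g: float(data.values[GENES.index(g), :, day_sel].max())
        for g in GENES
    }
    kms = initialize_km(problem.gene, typical, problem.topology, problem.bounds)
    lo_b, hi_b = problem.bounds.beta
    lo_d, hi_d = problem.bounds.dc
    if dc0 is None:
        dc0 = float(np.sqrt(lo_d * hi_d))
    n_act = len(problem.topology.activators[problem.gene])
    beta0 = float(np.clip(dc0 * typical[problem.gene] / n_act, lo_b, hi_b))
    theta = [beta0] * n_act + kms + [dc0]
    names = parameter_names(problem.gene, problem.topology)
    if names[-1] in ("p2", "p4"):
        # crude trigger scale: largest day-over-day rise in the data
        rises = np.diff(problem.data.values[GENES.index(problem.gene)], axis=1)
        theta.append(max(float(rises.max()), 1.0))
    return np.asarray(theta)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_equation(
    problem: EstimationProblem,
    initial: np.ndarray | None = None,
    restarts: int = 0,
    seed: int = 0,
    jitter: float = 2.0,
    optimizer_options: dict | None = None,
) -> FitResult:
    """Bounded nonlinear least squares on one decoupled equation.

    With ``initial=None`` the start is the gradient-matching pre-fit plus a
    deterministic sweep over log-spaced decay rates (the landscape is
    multimodal; the latching/non-latching basins differ mainly in the
    beta/dc balance).  ``restarts`` > 0 adds seeded multistarts that jitter
    the starting point by factors in [1/jitter, jitter] per parameter; the
    best objective wins.
    """
    model = _DecoupledModel(problem)
    lo, hi = _bounds_vectors(problem.gene, problem.topology, problem.bounds)

    def clip(theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, lo, np.where(np.isfinite(hi), hi, theta))

    starts: list[np.ndarray] = []
    if initial is None:
        theta0 = clip(gradient_match_initial(problem))
        starts.append(theta0)
        lo_d, hi_d = problem.bounds.dc
        for dc0 in np.exp(np.linspace(np.log(lo_d * 1.5), np.log(hi_d / 1.5), 4)):
            starts.append(clip(_default_initial(problem, dc0=dc0)))
    else:
        theta0 = clip(np.asarray(initial, float))
        starts.append(theta0)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        factors = np.exp(rng.uniform(-np.log(jitter), np.log(jitter),
                                     size=theta0.shape))
        starts.append(clip(theta0 * factors))

    opts = {"xtol": 1e-10, "ftol": 1e-10, "gtol": 1e-10, "x_scale": "jac",
            "max_nfev": 400}
    opts.update(optimizer_options or {})
    best = None
    n_evals = 0
    for start in starts:
        try:
            res = least_squares(model.residuals, start, bounds=(lo, hi), **opts)
        except RuntimeError:
            continue
        n_evals += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all fits failed for gene {problem.gene}")

    names = parameter_names(problem.gene, problem.topology)
    at_bound = {}
    for name, v, l, h in zip(names, best.x, lo, hi):
        if np.isclose(v, l, rtol=1e-6):
            at_bound[name] = "lower"
        elif np.isfinite(h) and np.isclose(v, h, rtol=1e-6):
            at_bound[name] = "upper"
    return FitResult(
        gene=problem.gene,
        parameters=dict(zip(names, best.x)),
        objective=float(2.0 * best.cost),
        at_bound=at_bound,
        success=bool(best.status > 0),
        message=str(best.message),
        n_evaluations=n_evals,
    )


def _assemble(
    fits: Mapping[str, FitResult], topology: NetworkTopology
) -> KineticParameters:
    beta, km_act, km_rep, dc = {}, {}, {}, {}
    p2 = p4 = 1.0
    for g in GENES:
        p = fits[g].parameters
        beta[g] = tuple(p[f"beta:{d}"] for d in topology.activators[g])
        km_act[g] = tuple(p[f"km_act:{d}"] for d in topology.activators[g])
        km_rep[g] = tuple(p[f"km_rep:{d}"] for d in topology.repressors[g])
        dc[g] = p["dc"]
        if g == "AP3":
            p2 = p["p2"]
        elif g == "AG":
            p4 = p["p4"]
    return KineticParameters(beta=beta, km_act=km_act, km_rep=km_rep, dc=dc,
                             p2_magnitude=p2, p4_magnitude=p4)


def fit_all(
    totals: ConcentrationGrid,
    topology: NetworkTopology,
    bounds: ParameterBounds | None = None,
    schedule: TriggerSchedule | None = None,
    restarts: int = 0,
    seed: int = 0,
    jitter: float = 2.0,
    initial: Mapping[str, np.ndarray] | None = None,
    optimizer_options: dict | None = None,
) -> tuple[KineticParameters, dict[str, FitResult]]:
    """Run the six decoupled fits and assemble a full kinetic set.

    The fits are independent by construction (no parameter is shared
    between equations), so the gene order is immaterial.  ``totals`` is the
    measured total-concentration grid; monomer data are derived internally.
    """
    bounds = bounds or ParameterBounds()
    schedule = schedule or TriggerSchedule()
    monomers = monomer_data(totals, topology)
    fits: dict[str, FitResult] = {}
    for g in GENES:
        problem = EstimationProblem(gene=g, data=monomers, topology=topology,
                                    schedule=schedule, bounds=bounds)
        fits[g] = fit_equation(
            problem,
            initial=None if initial is None else initial.get(g),
            restarts=restarts,
            seed=seed + GENE_INDEX[g],
            jitter=jitter,
            optimizer_options=optimizer_options,
        )
    return _assemble(fits, topology), fits
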