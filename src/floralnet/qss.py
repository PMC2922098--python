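"""Quasi-steady-state reduction of the dimer kinetics.

Dimerization (koff ~ 1/min) is fast compared with transcription and decay
(day scale), so each dimer tracks its monomers instantaneously:
[x_i x_j] = gamma_ij * x_i * x_j.  Substituting this into the monomer
balance turns the 13-state coupled system into 6 implicit ODEs; collecting
the monomer derivatives yields the mass-matrix form

    M(x) dx/dt = g(x, t),

where g is production + trigger - decay and M absorbs the dimerization
fluxes.  M is strictly diagonally dominant by columns for x >= 0, hence
always invertible, and the reduced system is integrated as an ordinary
explicit ODE with a 6x6 linear solve per right-hand-side evaluation.

The same algebra gives the conversion between monomer concentrations and
the total (monomer + dimer-bound) concentrations the data report: the
forward map is a polynomial mass balance, the inverse a damped Newton
iteration whose Jacobian is exactly M(x).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .network import (
    GENE_INDEX,
    KineticParameters,
    NetworkTopology,
    Trajectory,
    TriggerSchedule,
    _integrate_piecewise,
    _production_vector,
)

__all__ = [
    "qss_dimer",
    "qss_dimer_vector",
    "totals_from_monomers",
    "monomers_from_totals",
    "mass_matrix",
    "simulate_reduced",
]


def qss_dimer(x_i: float, x_j: float, gamma: float) -> float:
    """Quasi-steady-state dimer concentration gamma * x_i * x_j (nM).

    For a homodimer pass the same concentration twice (gamma * x_i**2).
    """
    if np.any(np.asarray(x_i) < 0) or np.any(np.asarray(x_j) < 0):
        raise ValueError("monomer concentrations must be non-negative")
    return gamma * x_i * x_j


def qss_dimer_vector(x: np.ndarray, topology: NetworkTopology) -> np.ndarray:
    """All 7 QSS dimer concentrations for a monomer 6-vector."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(topology.dimers))
    for j, spec in enumerate(topology.dimers):
        ia = GENE_INDEX[spec.partners[0]] - 1
        ib = GENE_INDEX[spec.partners[1]] - 1
        out[j] = spec.gamma * x[ia] * x[ib]
    return out


def totals_from_monomers(x: np.ndarray, topology: NetworkTopology) -> np.ndarray:
    """Total concentration per gene: monomer plus dimer-bound content.

    total_i = x_i + sum_heterodimers gamma*x_i*x_partner + 2*gamma_ii*x_i^2.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("monomer concentrations must be non-negative")
    d = qss_dimer_vector(x, topology)
    tot = x.copy()
    for j, spec in enumerate(topology.dimers):
        for partner in set(spec.partners):
            tot[GENE_INDEX[partner] - 1] += spec.stoichiometry(partner) * d[j]
    return tot


def mass_matrix(x: np.ndarray, topology: NetworkTopology) -> np.ndarray:
    """State-dependent mass matrix M(x) of the reduced system.

    M_ii = 1 + sum_{heterodimer partners j} gamma_ij x_j + 4 gamma_ii x_i,
    M_ij = gamma_ij x_i.  M is also the Jacobian of
    :func:`totals_from_monomers`; it is strictly diagonally dominant by
    columns for non-negative x, hence invertible.
    """
    x = np.asarray(x, dtype=float)
    M = np.eye(6)
    for spec in topology.dimers:
        ia = GENE_INDEX[spec.partners[0]] - 1
        ib = GENE_INDEX[spec.partners[1]] - 1
        if spec.is_homodimer:
            M[ia, ia] += 4.0 * spec.gamma * x[ia]
        else:
            M[ia, ia] += spec.gamma * x[ib]
            M[ib, ib] += spec.gamma * x[ia]
            M[ia, ib] += spec.gamma * x[ia]
            M[ib, ia] += spec.gamma * x[ib]
    return M


def monomers_from_totals(
    totals: np.ndarray,
    topology: NetworkTopology,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Invert the mass balance: recover monomers from total concentrations.

    Damped Newton iteration with positivity projection; the initial guess
    x = totals is exact when all gamma vanish.  Convergence criterion:
    residual sup-norm <= tol * (1 + ||totals||_inf).
    """
    T = np.asarray(totals, dtype=float)
    if (T < 0).any():
        raise ValueError("total concentrations must be non-negative")
    x = T.copy()
    scale = 1.0 + np.max(np.abs(T), initial=0.0)
    res = totals_from_monomers(x, topology) - T
    best = np.max(np.abs(res))
    for _ in range(max_iter):
        if best <= tol * scale:
            return x
        step = np.linalg.solve(mass_matrix(x, topology), res)
        lam = 1.0
        while lam > 1e-12:
            x_new = np.maximum(x - lam * step, 0.0)
            res_new = totals_from_monomers(x_new, topology) - T
            if np.max(np.abs(res_new)) < best:
                x, res, best = x_new, res_new, np.max(np.abs(res_new))
                break
            lam *= 0.5
        else:
            break
    if best > tol * scale:
        raise RuntimeError(
            f"mass-balance inversion did not converge: residual {best:.3e} "
            f"(tolerance {tol * scale:.3e})"
        )
    return x


def reduced_rhs(
    t: float,
    x: np.ndarray,
    whorl: int,
    topology: NetworkTopology,
    params: KineticParameters,
    schedule: TriggerSchedule,
    pinned: dict[int, float] | None = None,
) -> np.ndarray:
    """dx/dt = M(x)^{-1} g(x, t) for the reduced 6-monomer system.

    ``pinned`` maps gene indices (0-based) to fixed concentrations whose
    derivative is forced to zero (ectopic-expression experiments); their
    rows of the linear system are replaced by identity rows.
    """
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    dimer_conc = dict(zip(topology.dimer_names, qss_dimer_vector(x, topology)))
    g = _production_vector(x, dimer_conc, t, whorl, topology, params, schedule)
    M = mass_matrix(x, topology)
    if pinned:
        for i in pinned:
            M[i, :] = 0.0
            M[i, i] = 1.0
            g[i] = 0.0
    return np.linalg.solve(M, g)


def simulate_reduced(
    initial: np.ndarray,
    t_span: tuple[float, float],
    whorl: int,
    topology: NetworkTopology,
    params: KineticParameters,
    schedule: TriggerSchedule | None = None,
    t_eval: Iterable[float] | None = None,
    solver_options: dict | None = None,
    pinned: dict[int, float] | None = None,
) -> Trajectory:
    """Integrate the reduced 6-monomer system in one whorl.

    Returns a :class:`~floralnet.network.Trajectory` whose dimer block
    holds the QSS dimer concentrations derived from the monomers.
    """
    schedule = schedule or TriggerSchedule()
    x0 = np.asarray(initial, dtype=float).copy()
    if x0.shape != (6,):
        raise ValueError("reduced-model initial state must have 6 entries")
    if (x0 < 0).any():
        raise ValueError("negative concentrations rejected")
    if pinned:
        for i, level in pinned.items():
            x0[i] = level
    if t_eval is None:
        t_eval = np.arange(t_span[0], t_span[1] + 1e-9, 0.01)
    t_eval = np.asarray(list(t_eval), dtype=float)

    def rhs(t, x):
        return reduced_rhs(t, x, whorl, topology, params, schedule, pinned=pinned)

    t, X = _integrate_piecewise(rhs, t_span, x0, t_eval, schedule.edges, solver_options)
    X = np.maximum(X, 0.0)
    if pinned:  # guard against solver drift on the pinned coordinates
        for i, level in pinned.items():
            X[:, i] = level
    dimers = np.vstack([qss_dimer_vector(row, topology) for row in X])
    return Trajectory(whorl=whorl, times=t, monomers=X, dimers=dimers,
                      topology=topology)
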