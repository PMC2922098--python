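"""Synthetic ground-truth data generator.

The original expression series is literature microarray data without a
public accession, so the pipeline is exercised on synthetic data that
emulate its documented shape: daily samples over days 0-5, four whorls,
six genes, on-levels near 1e3 nM totals, off-levels at 1% of on-levels,
and volume-weighted meristem averages.  Trajectories are generated from
the packaged reference kinetics (so ground truth is known exactly),
sampled as total concentrations, and optionally corrupted with seeded
multiplicative log-normal noise — concentrations are positive and span
two decades, so additive noise would be ill-posed.

Day-0 convention: expression is spatially uniform; AP1 (induced at time 0)
and the ever-present SEP start at the on-level, the other genes at the 1%
off-level, identically in all whorls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    GENES,
    KineticParameters,
    NetworkTopology,
    Trajectory,
    TriggerSchedule,
)
from .presets import reference_parameters
from .qss import monomers_from_totals, simulate_reduced
from .transform import (
    WHORLS,
    ConcentrationGrid,
    MeristemAverageSeries,
    WhorlGeometry,
)

__all__ = [
    "SyntheticConfig",
    "initial_totals",
    "initial_monomers",
    "simulate_wild_type",
    "generate_truth",
    "add_noise",
    "meristem_average",
]


@dataclass
class SyntheticConfig:
    """Generator settings: kinetics, noise level, seed, sampling grid."""

    topology: NetworkTopology | None = None
    params: KineticParameters | None = None
    schedule: TriggerSchedule = field(default_factory=TriggerSchedule)
    sigma: float = 0.05
    seed: int = 0
    sampling_days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    on_level: float = 1.0e3
    off_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.topology is None:
            from .network import build_default_topology

            self.topology = build_default_topology()
        if self.params is None:
            self.params = reference_parameters()
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def initial_totals(config: SyntheticConfig) -> np.ndarray:
    """Day-0 total concentrations (nM), identical in every whorl."""
    off = config.off_fraction * config.on_level
    levels = {g: off for g in GENES}
    levels["AP1"] = config.on_level
    levels["SEP"] = config.on_level
    return np.array([levels[g] for g in GENES])


def initial_monomers(config: SyntheticConfig) -> np.ndarray:
    """Day-0 monomer concentrations from inverting the mass balance."""
    return monomers_from_totals(initial_totals(config), config.topology)


def simulate_wild_type(
    config: SyntheticConfig | None = None,
    t_end: float = 5.0,
    t_eval: np.ndarray | None = None,
) -> dict[int, Trajectory]:
    """Reduced-model wild-type trajectories for all four whorls."""
    config = config or SyntheticConfig()
    x0 = initial_monomers(config)
    return {
        w: simulate_reduced(
            x0, (0.0, t_end), w, config.topology, config.params, config.schedule,
            t_eval=t_eval,
        )
        for w in WHORLS
    }


def generate_truth(config: SyntheticConfig | None = None) -> ConcentrationGrid:
    """Noise-free total-concentration grid (gene, whorl, day).

    Simulates the reduced model per whorl from the day-0 convention and
    samples total concentrations at ``config.sampling_days``.
    """
    config = config or SyntheticConfig()
    days = np.asarray(config.sampling_days, dtype=float)
    t_end = float(days.max())
    trajectories = simulate_wild_type(config, t_end=t_end, t_eval=days)
    values = np.empty((len(GENES), len(WHORLS), len(days)))
    for w in WHORLS:
        totals = trajectories[w].totals()  # (D, 6)
        values[:, w - 1, :] = totals.T
    return ConcentrationGrid(values=values, days=tuple(config.sampling_days))


def add_noise(grid: ConcentrationGrid, config: SyntheticConfig) -> ConcentrationGrid:
    """Multiply each grid entry by exp(N(0, sigma^2)) with a seeded RNG.

    sigma = 0 returns the grid unchanged; the log of the noisy value is an
    unbiased estimate of the log of the truth.
    """
    if (grid.values <= 0).any():
        raise ValueError("noise model requires strictly positive concentrations")
    if config.sigma == 0:
        return ConcentrationGrid(values=grid.values.copy(), days=grid.days)
    rng = np.random.default_rng(config.seed)
    factors = np.exp(rng.normal(0.0, config.sigma, size=grid.values.shape))
    return ConcentrationGrid(values=grid.values * factors, days=grid.days)


def meristem_average(
    grid: ConcentrationGrid, geometry: WhorlGeometry | None = None
) -> MeristemAverageSeries:
    """Volume-weighted whorl mean per gene/day — the forward mass balance
    that the whorl reconstruction inverts."""
    geometry = geometry or WhorlGeometry()
    weights = geometry.weights  # (4,)
    values = np.einsum("gwd,w->gd", grid.values, weights)
    return MeristemAverageSeries(values=values, days=grid.days)
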