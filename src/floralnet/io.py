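"""Readers/writers and run manifests shared by all pipeline stages.

Trajectory CSV dialect (tidy): columns
``whorl, gene, time_days, concentration_nM, species`` with species one of
``monomer``, ``dimer:[A B]`` or ``total``.  Round trips are lossless to 12
significant digits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .network import GENES, NetworkTopology, Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_manifest",
    "topology_config",
]

_COLUMNS = ["whorl", "gene", "time_days", "concentration_nM", "species"]


def trajectory_frame(trajectories: Mapping[int, Trajectory]) -> pd.DataFrame:
    """Tidy frame with monomer, per-dimer and total species rows."""
    chunks = []
    for w, traj in sorted(trajectories.items()):
        totals = traj.totals()
        for i, g in enumerate(GENES):
            chunks.append(pd.DataFrame({
                "whorl": w, "gene": g, "time_days": traj.times,
                "concentration_nM": traj.monomers[:, i], "species": "monomer",
            }))
            chunks.append(pd.DataFrame({
                "whorl": w, "gene": g, "time_days": traj.times,
                "concentration_nM": totals[:, i], "species": "total",
            }))
        for j, name in enumerate(traj.topology.dimer_names):
            a = name.strip("[]").split()[0]
            chunks.append(pd.DataFrame({
                "whorl": w, "gene": a, "time_days": traj.times,
                "concentration_nM": traj.dimers[:, j], "species": f"dimer:{name}",
            }))
    return pd.concat(chunks, ignore_index=True)[_COLUMNS]


def write_trajectory_csv(
    trajectories: Mapping[int, Trajectory], path: str | Path
) -> Path:
    path = Path(path)
    frame = trajectory_frame(trajectories)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy trajectory CSV.

    Returns the validated frame; malformed headers, unknown genes or
    negative concentrations are rejected with the offending row number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    if frame.empty:
        raise ValueError(f"{path}: empty trajectory file")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing column(s) {missing}")
    bad_gene = ~frame["gene"].isin(GENES)
    if bad_gene.any():
        row = int(frame.index[bad_gene][0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: unknown gene {frame.loc[bad_gene, 'gene'].iloc[0]!r} at row {row}"
        )
    negative = frame["concentration_nM"] < 0
    if negative.any():
        row = int(frame.index[negative][0]) + 2
        raise ValueError(f"{path}: negative concentration at row {row}")
    return frame


def topology_config(topology: NetworkTopology) -> dict:
    """JSON/YAML-ready description of a topology, gamma assignment explicit."""
    return {
        "genes": list(topology.genes),
        "dimers": [
            {"name": d.name, "gamma_per_nM": d.gamma, "koff_per_day": d.koff}
            for d in topology.dimers
        ],
        "activators": {g: list(v) for g, v in topology.activators.items()},
        "repressors": {g: list(v) for g, v in topology.repressors.items()},
    }


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    command: str
    config: dict
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        body = {"command": self.command, "config": self.config,
                "seed": self.seed, "outputs": self.outputs}
        digest = hashlib.sha256(
            json.dumps(body, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {**body, "config_sha256": digest}


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest.to_dict(), indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
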