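"""Distance featurization of dimer trajectories.

The kinetic feature set is the four inter-monomer domain centre-of-mass
distances, in the fixed column order

    0: A.Ntd - B.Ntd
    1: A.Ntd - B.Ctd
    2: A.Ctd - B.Ntd
    3: A.Ctd - B.Ctd

plus, for event detection and population histograms, the whole-monomer
COM distance. All distances are mass-weighted (geometric COM available via
``mass_weighted=False``) and reported in nm. Terminal-arm beads are excluded
from domain COMs; they do contribute to whole-monomer COMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import (
    Topology,
    TrajectoryEnsemble,
    read_annotation_table,
    read_topology_pdb,
    read_trajectories,
    topology_from_annotation,
)

#: (chain, domain) pairs for each feature column, in the documented order.
FEATURE_PAIRS = (
    (("A", "Ntd"), ("B", "Ntd")),
    (("A", "Ntd"), ("B", "Ctd")),
    (("A", "Ctd"), ("B", "Ntd")),
    (("A", "Ctd"), ("B", "Ctd")),
)

#: Column permutation under a chain A<->B swap (column 2 and 3 exchange).
CHAIN_SWAP_PERMUTATION = (0, 2, 1, 3)


@dataclass
class FeatureMatrix:
    """Per-replica ``(T, 4)`` inter-domain COM distances in nm."""

    replicas: list[np.ndarray]
    frame_interval: float

    def __post_init__(self) -> None:
        clean = []
        for r, X in enumerate(self.replicas):
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if np.any(X < 0):
                raise ValueError(f"replica {r}: negative distances")
            clean.append(X)
        self.replicas = clean
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_features(self) -> int:
        return self.replicas[0].shape[1]

    def pooled(self) -> np.ndarray:
        """All replicas concatenated along time (for histograms, clustering)."""
        return np.concatenate(self.replicas, axis=0)


def load_trajectories(topology_path: str | Path,
                      trajectory_paths: list[str | Path] | str | Path,
                      domain_map: str | Path | pd.DataFrame) -> TrajectoryEnsemble:
    """Assemble a validated ensemble from PDB + container files + annotation.

    The PDB supplies the bead count (and a reference frame); the annotation
    table supplies chain/domain/mass/residue per bead; the ``.npz`` container
    files supply coordinates. All container files must share one frame
    interval.
    """
    coords, _ = read_topology_pdb(topology_path)
    if isinstance(domain_map, pd.DataFrame):
        table = domain_map
    else:
        table = read_annotation_table(domain_map)
    topology = topology_from_annotation(table, n_beads=coords.shape[0])
    topology.validate_dimer()

    if isinstance(trajectory_paths, (str, Path)):
        trajectory_paths = [trajectory_paths]
    replicas: list[np.ndarray] = []
    interval = None
    for p in trajectory_paths:
        reps, dt = read_trajectories(p)
        if interval is None:
            interval = dt
        elif not np.isclose(interval, dt):
            raise ValueError(
                f"{p}: frame interval {dt} ns differs from previous files ({interval} ns)"
            )
        replicas.extend(reps)
    assert interval is not None
    return TrajectoryEnsemble(replicas=replicas, frame_interval=interval,
                              topology=topology)


def _com_series(xyz: np.ndarray, mask: np.ndarray, masses: np.ndarray,
                mass_weighted: bool) -> np.ndarray:
    """Per-frame COM of the selected beads; ``(T, 3)``."""
    if not np.any(mask):
        raise ValueError("empty bead selection for COM")
    sub = xyz[:, mask, :]
    if mass_weighted:
        w = masses[mask]
        return np.einsum("tbi,b->ti", sub, w) / w.sum()
    return sub.mean(axis=1)


def domain_com_distances(ensemble: TrajectoryEnsemble,
                         mass_weighted: bool = True) -> FeatureMatrix:
    """The four inter-monomer domain COM distances per frame.

    Arm beads never enter domain COMs: the kinetic feature is the distance
    between the globular N- and C-terminal domains of the two monomers.
    """
    top = ensemble.topology
    top.validate_dimer()
    masks = {(c, d): top.select(chain=c, domain=d)
             for c in ("A", "B") for d in ("Ntd", "Ctd")}
    out = []
    for xyz in ensemble.replicas:
        coms = {key: _com_series(xyz, mask, top.masses, mass_weighted)
                for key, mask in masks.items()}
        cols = [np.linalg.norm(coms[a] - coms[b], axis=1) for a, b in FEATURE_PAIRS]
        out.append(np.stack(cols, axis=1))
    return FeatureMatrix(replicas=out, frame_interval=ensemble.frame_interval)


def monomer_com_distance(ensemble: TrajectoryEnsemble,
                         mass_weighted: bool = True) -> list[np.ndarray]:
    """Whole-chain COM distance per frame, one 1-D series per replica (nm)."""
    top = ensemble.topology
    top.validate_dimer()
    mask_a = top.select(chain="A")
    mask_b = top.select(chain="B")
    series = []
    for xyz in ensemble.replicas:
        com_a = _com_series(xyz, mask_a, top.masses, mass_weighted)
        com_b = _com_series(xyz, mask_b, top.masses, mass_weighted)
        series.append(np.linalg.norm(com_a - com_b, axis=1))
    return series
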