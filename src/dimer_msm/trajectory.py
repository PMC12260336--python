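"""Trajectory containers and topology I/O.

Coordinates are stored per replica as ``(n_frames, n_beads, 3)`` float arrays
in nanometres, with a single shared topology describing each bead's chain
(``A`` or ``B``), domain (``Ntd``, ``Ctd`` or ``arm``), mass and residue id.
Trajectories round-trip through a documented NumPy ``.npz`` container;
reference topologies round-trip through PDB (Angstrom on disk, converted to
nm on load) via MDAnalysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHAINS = ("A", "B")
DOMAINS = ("Ntd", "Ctd", "arm")

#: Angstrom per nanometre; PDB files are Angstrom, everything in memory is nm.
_ANG_PER_NM = 10.0


@dataclass
class Topology:
    """Per-bead annotation shared by every replica of an ensemble.

    Parameters
    ----------
    chain_ids : array of str
        ``"A"`` or ``"B"`` per bead.
    domain_ids : array of str
        ``"Ntd"``, ``"Ctd"`` or ``"arm"`` per bead. Arm beads are excluded
        from domain centres of mass by default.
    masses : array of float
        Bead masses (arbitrary units; only ratios matter for COMs).
    residue_ids : array of int, optional
        Residue index per bead, used by contact-map analysis. Defaults to one
        residue per bead.
    """

    chain_ids: np.ndarray
    domain_ids: np.ndarray
    masses: np.ndarray
    residue_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.domain_ids = np.asarray(self.domain_ids, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.residue_ids is None:
            self.residue_ids = np.arange(self.n_beads)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if not (len(self.chain_ids) == len(self.domain_ids) == len(self.masses)
                == len(self.residue_ids)):
            raise ValueError("topology columns have inconsistent lengths")
        bad_chain = set(self.chain_ids) - set(CHAINS)
        if bad_chain:
            raise ValueError(f"unknown chain ids {sorted(bad_chain)}; expected {CHAINS}")
        bad_dom = set(self.domain_ids) - set(DOMAINS)
        if bad_dom:
            raise ValueError(f"unknown domain ids {sorted(bad_dom)}; expected {DOMAINS}")
        if np.any(self.masses <= 0):
            raise ValueError("bead masses must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.chain_ids)

    def select(self, chain: str | None = None, domain: str | None = None) -> np.ndarray:
        """Boolean mask of beads matching the given chain and/or domain."""
        mask = np.ones(self.n_beads, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if domain is not None:
            mask &= self.domain_ids == domain
        return mask

    def validate_dimer(self) -> None:
        """Require both chains present with annotated Ntd and Ctd domains."""
        for chain in CHAINS:
            if not np.any(self.chain_ids == chain):
                raise ValueError(f"chain {chain} missing from topology")
            for domain in ("Ntd", "Ctd"):
                mask = self.select(chain=chain, domain=domain)
                if not np.any(mask):
                    raise ValueError(f"chain {chain} has no beads annotated {domain}")
                if self.masses[mask].sum() <= 0:
                    raise ValueError(f"chain {chain} domain {domain} has zero mass")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead": np.arange(self.n_beads),
                "chain": self.chain_ids,
                "domain": self.domain_ids,
                "mass": self.masses,
                "residue": self.residue_ids,
            }
        )


@dataclass
class TrajectoryEnsemble:
    """Multi-replica coordinate time series over one shared topology.

    ``replicas`` is a list of ``(n_frames, n_beads, 3)`` arrays in nm;
    ``frame_interval`` is the time between stored frames in ns.
    """

    replicas: list[np.ndarray]
    frame_interval: float
    topology: Topology

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ns)")
        if not self.replicas:
            raise ValueError("ensemble holds no replicas")
        clean = []
        for r, xyz in enumerate(self.replicas):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[2] != 3:
                raise ValueError(f"replica {r}: expected (frames, beads, 3), got {xyz.shape}")
            if xyz.shape[1] != self.topology.n_beads:
                raise ValueError(
                    f"replica {r}: {xyz.shape[1]} beads but topology has "
                    f"{self.topology.n_beads}"
                )
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"replica {r}: non-finite coordinates")
            clean.append(xyz)
        self.replicas = clean

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames(self) -> list[int]:
        return [xyz.shape[0] for xyz in self.replicas]

    @property
    def replica_lengths_ns(self) -> list[float]:
        return [n * self.frame_interval for n in self.n_frames]

    @property
    def total_time_ns(self) -> float:
        """Aggregate simulated time over all replicas, in ns."""
        return float(sum(self.replica_lengths_ns))

    def protocol_summary(self) -> dict:
        """Replica bookkeeping: counts, per-replica lengths, aggregate time."""
        lengths = self.replica_lengths_ns
        return {
            "n_replicas": self.n_replicas,
            "frame_interval_ns": self.frame_interval,
            "replica_length_ns": lengths,
            "total_time_ns": self.total_time_ns,
            "total_time_us": self.total_time_ns / 1e3,
        }


def write_trajectories(ensemble: TrajectoryEnsemble, path: str | Path) -> Path:
    """Write replica coordinates to the package's ``.npz`` container."""
    path = Path(path)
    arrays = {f"replica_{i:03d}": xyz for i, xyz in enumerate(ensemble.replicas)}
    arrays["frame_interval_ns"] = np.asarray(ensemble.frame_interval)
    np.savez(path, **arrays)
    return path


def read_trajectories(path: str | Path) -> tuple[list[np.ndarray], float]:
    """Read replica coordinates and frame interval from the ``.npz`` container."""
    with np.load(Path(path)) as data:
        keys = sorted(k for k in data.files if k.startswith("replica_"))
        if not keys:
            raise ValueError(f"{path}: no replica_* arrays found")
        replicas = [data[k] for k in keys]
        interval = float(data["frame_interval_ns"])
    return replicas, interval


def write_topology_pdb(topology: Topology, coordinates_nm: np.ndarray,
                       path: str | Path) -> Path:
    """Write a single reference frame as PDB (coordinates converted to Angstrom)."""
    import MDAnalysis as mda

    n = topology.n_beads
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int), trajectory=True)
    u.add_TopologyAttr("name", ["BB"] * n)
    u.add_TopologyAttr("resname", [str(d)[:3].upper() for d in topology.domain_ids])
    u.add_TopologyAttr("resid", topology.residue_ids + 1)
    u.add_TopologyAttr("chainID", [str(c) for c in topology.chain_ids])
    u.add_TopologyAttr("mass", topology.masses)
    u.atoms.positions = np.asarray(coordinates_nm, dtype=float) * _ANG_PER_NM
    u.atoms.write(str(path))
    return Path(path)


def read_topology_pdb(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read reference coordinates (nm) and chain ids from a PDB file."""
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = u.atoms.positions / _ANG_PER_NM
        chains = np.asarray([str(c) for c in u.atoms.chainIDs], dtype=object)
    return coords, chains


def write_annotation_table(topology: Topology, path: str | Path) -> Path:
    """Write the bead/chain/domain (plus mass, residue) annotation as TSV."""
    topology.to_frame().to_csv(path, sep="\t", index=False)
    return Path(path)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"bead", "chain", "domain"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    return table


def topology_from_annotation(table: pd.DataFrame, n_beads: int | None = None) -> Topology:
    """Build a :class:`Topology` from a 3+ column annotation table.

    Masses default to 1 and residues to one per bead when the optional
    columns are absent.
    """
    table = table.sort_values("bead").reset_index(drop=True)
    if n_beads is not None:
        covered = set(table["bead"].tolist())
        expected = set(range(n_beads))
        if covered != expected:
            missing = sorted(expected - covered)
            raise ValueError(f"annotation does not cover beads {missing[:10]}")
    masses = table["mass"].to_numpy(float) if "mass" in table else np.ones(len(table))
    residues = (table["residue"].to_numpy(int) if "residue" in table
                else np.arange(len(table)))
    return Topology(
        chain_ids=table["chain"].to_numpy(object),
        domain_ids=table["domain"].to_numpy(object),
        masses=masses,
        residue_ids=residues,
    )


def write_manifest(path: str | Path, **entries) -> Path:
    """Record seeds, parameters and the replica plan as JSON."""
    path = Path(path)
    path.write_text(json.dumps(entries, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
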