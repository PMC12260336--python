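"""Structural observables: association events, populations, contacts, RMSD.

Binding/unbinding events on the monomer-monomer COM distance use dual
hysteresis thresholds — enter "bound" below the dimeric cutoff (6 nm by
default), "unbound" above the monomeric cutoff (7 nm) — so that frames
inside the band never toggle the state and event counts are chatter-free.
Contact maps follow the standard convention: a residue pair is in contact in
a frame when its minimum inter-atom distance falls below the cutoff
(0.45 nm default), and pairs are reported when their contact fraction over
frames exceeds a threshold (0.75 default). RMSD uses Kabsch superposition
with the proper-rotation determinant correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import TrajectoryEnsemble

#: Default dimeric / monomeric distance cutoffs (nm).
BOUND_THRESHOLD_NM = 6.0
UNBOUND_THRESHOLD_NM = 7.0

#: Default contact-map settings.
CONTACT_CUTOFF_NM = 0.45
CONTACT_FRACTION_THRESHOLD = 0.75


@dataclass
class EventSeries:
    """Dwell segments and transition counts per replica.

    ``segments[r]`` is a list of ``(state, start_ns, end_ns)`` tuples tiling
    replica r without overlap; states are "bound", "unbound" or
    "intermediate" (initial frames inside the hysteresis band).
    """

    segments: list[list[tuple[str, float, float]]]
    n_binding: int
    n_unbinding: int

    def dwell_time_ns(self, state: str) -> float:
        return sum(end - start
                   for replica in self.segments
                   for s, start, end in replica if s == state)


def _label_series(d: np.ndarray, bound_thr: float, unbound_thr: float) -> np.ndarray:
    states = np.empty(len(d), dtype=object)
    current = "intermediate"
    for t, x in enumerate(d):
        if x < bound_thr:
            current = "bound"
        elif x > unbound_thr:
            current = "unbound"
        states[t] = current
    return states


def detect_association_events(distance: list[np.ndarray], frame_interval: float,
                              bound_thr: float = BOUND_THRESHOLD_NM,
                              unbound_thr: float = UNBOUND_THRESHOLD_NM) -> EventSeries:
    """Hysteresis state machine over per-replica COM distance series.

    A binding event is an unbound->bound transition (crossing below
    ``bound_thr`` after having been above ``unbound_thr``); an unbinding
    event is the reverse. In-band frames keep the previous state.
    """
    if unbound_thr <= bound_thr:
        raise ValueError("unbound_thr must exceed bound_thr (hysteresis band)")
    segments = []
    n_bind = n_unbind = 0
    for d in distance:
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise ValueError("empty distance series")
        states = _label_series(d, bound_thr, unbound_thr)
        reps = []
        start = 0
        for t in range(1, len(states) + 1):
            if t == len(states) or states[t] != states[start]:
                reps.append((states[start], start * frame_interval,
                             t * frame_interval))
                if t < len(states):
                    if states[start] == "unbound" and states[t] == "bound":
                        n_bind += 1
                    elif states[start] == "bound" and states[t] == "unbound":
                        n_unbind += 1
                    elif states[start] == "intermediate":
                        pass  # first crossing, not an event
                start = t
        segments.append(reps)
    return EventSeries(segments=segments, n_binding=n_bind, n_unbinding=n_unbind)


@dataclass
class PopulationResult:
    """Distance histogram plus bound/unbound population fractions."""

    bin_edges: np.ndarray
    density: np.ndarray
    bound_fraction: float
    unbound_fraction: float
    intermediate_fraction: float


def population_fractions(distance: np.ndarray | list[np.ndarray],
                         bound_thr: float = BOUND_THRESHOLD_NM,
                         unbound_thr: float = UNBOUND_THRESHOLD_NM,
                         bin_width: float = 0.1) -> PopulationResult:
    """Normalized distance histogram and threshold population fractions.

    Fractions are P(d < bound_thr), P(d > unbound_thr) and the in-band rest;
    the three sum to 1 exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(distance, list):
        distance = np.concatenate([np.asarray(d).ravel() for d in distance])
    d = np.asarray(distance, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty distance data")
    lo = 0.0
    hi = max(d.max(), unbound_thr) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    bound = float(np.mean(d < bound_thr))
    unbound = float(np.mean(d > unbound_thr))
    return PopulationResult(
        bin_edges=edges, density=density, bound_fraction=bound,
        unbound_fraction=unbound,
        intermediate_fraction=1.0 - bound - unbound,
    )


@dataclass
class ContactMap:
    """Inter-chain residue contact fractions and the filtered pair list."""

    residues_a: np.ndarray
    residues_b: np.ndarray
    fractions: np.ndarray          # (len(residues_a), len(residues_b)) in [0, 1]
    cutoff_nm: float
    fraction_threshold: float

    def filtered_pairs(self) -> pd.DataFrame:
        """Residue pairs whose contact fraction exceeds the threshold."""
        ia, ib = np.nonzero(self.fractions > self.fraction_threshold)
        return pd.DataFrame({
            "residue_a": self.residues_a[ia],
            "residue_b": self.residues_b[ib],
            "fraction": self.fractions[ia, ib],
        }).sort_values("fraction", ascending=False).reset_index(drop=True)


def interchain_contact_map(ensemble: TrajectoryEnsemble,
                           cutoff: float = CONTACT_CUTOFF_NM,
                           fraction_threshold: float = CONTACT_FRACTION_THRESHOLD,
                           ) -> ContactMap:
    """Residue-pair contact fractions between chains A and B.

    A pair is in contact in a frame when the minimum distance between any of
    its beads falls below ``cutoff``. Fractions pool all replicas.
    """
    top = ensemble.topology
    mask_a = top.select(chain="A")
    mask_b = top.select(chain="B")
    if not mask_a.any():
        raise ValueError("chain A missing from topology")
    if not mask_b.any():
        raise ValueError("chain B missing from topology")
    res_a = np.unique(top.residue_ids[mask_a])
    res_b = np.unique(top.residue_ids[mask_b])
    idx_a = {r: i for i, r in enumerate(res_a)}
    idx_b = {r: i for i, r in enumerate(res_b)}
    map_a = np.asarray([idx_a[r] for r in top.residue_ids[mask_a]])
    map_b = np.asarray([idx_b[r] for r in top.residue_ids[mask_b]])

    counts = np.zeros((res_a.size, res_b.size))
    n_frames = 0
    for xyz in ensemble.replicas:
        for frame in xyz:
            dist = cdist(frame[mask_a], frame[mask_b])
            mind = np.full((res_a.size, res_b.size), np.inf)
            np.minimum.at(mind, (map_a[:, None], map_b[None, :]), dist)
            counts += mind < cutoff
            n_frames += 1
    return ContactMap(
        residues_a=res_a, residues_b=res_b, fractions=counts / n_frames,
        cutoff_nm=cutoff, fraction_threshold=fraction_threshold,
    )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation aligning mobile onto reference.

    Returns (R, t, aligned) with aligned = (mobile - mobile_COM) @ R + ref_COM.
    The determinant correction guarantees det(R) = +1 (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: {mobile.shape[0]} vs {reference.shape[0]}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    aligned = (mobile - mc) @ R + rc
    return R, rc - mc @ R, aligned


def kabsch_rmsd(reference: np.ndarray, ensemble: TrajectoryEnsemble,
                chain: str | None = None, domain: str | None = None) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference after optimal superposition.

    ``reference`` holds one frame of coordinates for the full topology; the
    optional chain/domain selection restricts both fitting and measurement.
    Returns one concatenated series over all replicas.
    """
    top = ensemble.topology
    mask = top.select(chain=chain, domain=domain)
    if not mask.any():
        raise ValueError("empty selection for RMSD")
    ref = np.asarray(reference, dtype=float)[mask]
    out = []
    for xyz in ensemble.replicas:
        series = np.empty(xyz.shape[0])
        for t, frame in enumerate(xyz):
            _, _, aligned = kabsch_superpose(frame[mask], ref)
            series[t] = np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1)))
        out.append(series)
    return np.concatenate(out)
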