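"""Metastable coarse-graining and kinetics: PCCA++, committors, fluxes, MFPTs.

PCCA++ (Perron-cluster cluster analysis) groups microstates into metastable
macrostates from the dominant right eigenvectors of a reversible transition
matrix: rows of the eigenvector matrix live near the vertices of a simplex,
one vertex per metastable set; an inner-simplex vertex search picks the
spanning states, and the linear transform onto barycentric coordinates gives
fuzzy membership vectors, clipped to [0, 1] and renormalized.

Kinetic observables follow transition path theory on the microstate model:
forward committors q+ (probability of reaching B before A), gross/net
reactive fluxes f_ij = pi_i q-_i T_ij q+_j, and mean first passage times via
the absorbing linear system (I - T_restricted) m = tau 1, aggregated to
macrostates by stationary weighting over the source's crisp set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msm import MSMModel, _reversible_eigh, macrostate_free_energies

logger = logging.getLogger(__name__)


@dataclass
class MacrostateModel:
    """PCCA++ memberships and the derived crisp macrostate partition.

    Macrostates are numbered by descending stationary weight (macrostate 0 is
    the most populated). ``assignment`` maps each microstate of the model's
    active set to its macrostate; ``memberships`` rows are fuzzy and sum to 1.
    """

    memberships: np.ndarray
    assignment: np.ndarray
    stationary_weights: np.ndarray
    free_energies_kj_mol: np.ndarray
    temperature: float

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]

    def crisp_sets(self) -> list[np.ndarray]:
        """Microstate indices (into the active set) of each macrostate."""
        return [np.flatnonzero(self.assignment == m)
                for m in range(self.n_macrostates)]

    def relative_free_energies(self) -> np.ndarray:
        """Free energies shifted so the most stable macrostate sits at zero."""
        return self.free_energies_kj_mol - np.min(self.free_energies_kj_mol)


def _vertex_search(X: np.ndarray) -> np.ndarray:
    """Indices of rows of X spanning the largest simplex (PCCA++ index search).

    Start from the row farthest from the origin; repeatedly orthogonalize on
    the span found so far and take the row with the largest residual norm.
    """
    n, m = X.shape
    vertices = np.empty(m, dtype=int)
    W = X.copy()
    norms = np.linalg.norm(W, axis=1)
    vertices[0] = int(np.argmax(norms))
    W = W - W[vertices[0]]
    for j in range(1, m):
        norms = np.linalg.norm(W, axis=1)
        vertices[j] = int(np.argmax(norms))
        pivot = W[vertices[j]].copy()
        pnorm = np.linalg.norm(pivot)
        if pnorm == 0:
            raise np.linalg.LinAlgError("degenerate eigenvector rows in PCCA++")
        pivot /= pnorm
        W = W - np.outer(W @ pivot, pivot)
    return vertices


def pcca_plus(model: MSMModel, n_macrostates: int,
              temperature: float = 310.0) -> MacrostateModel:
    """Group microstates into metastable macrostates via PCCA++.

    Uses the ``n_macrostates`` dominant right eigenvectors of the reversible
    transition matrix. Deterministic given the model; degenerate eigenvalues
    are tie-broken by index order of the symmetric eigensolver.
    """
    n = model.n_states
    if not (1 <= n_macrostates <= n):
        raise ValueError(f"n_macrostates must lie in 1..{n}")
    lam, right = _reversible_eigh(model.transition_matrix,
                                  model.stationary_distribution)
    if n_macrostates > 1 and lam[n_macrostates - 1] <= 0:
        logger.warning(
            "requested %d macrostates but eigenvalue %d is %.3f <= 0; "
            "spectral support is questionable (eigenvalues: %s)",
            n_macrostates, n_macrostates, lam[n_macrostates - 1],
            np.array2string(lam[:n_macrostates + 1], precision=3),
        )
    X = right[:, :n_macrostates]
    # fix the trivial eigenvector to the exact constant
    X[:, 0] = 1.0

    vertices = _vertex_search(X)
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    row_sums = chi.sum(axis=1)
    if np.any(row_sums <= 0):
        raise np.linalg.LinAlgError("PCCA++ produced an all-zero membership row")
    chi = chi / row_sums[:, None]

    assignment = np.argmax(chi, axis=1)
    pi = model.stationary_distribution
    weights = np.array([pi[assignment == m].sum() for m in range(n_macrostates)])
    # renumber macrostates by descending stationary weight
    order = np.argsort(-weights, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(n_macrostates)
    chi = chi[:, order]
    assignment = rank[assignment]
    weights = weights[order]
    dg = macrostate_free_energies(pi, assignment, temperature)
    return MacrostateModel(
        memberships=chi, assignment=assignment, stationary_weights=weights,
        free_energies_kj_mol=dg, temperature=temperature,
    )


def markov_mfpt(transition_matrix: np.ndarray, source: np.ndarray,
                target: np.ndarray, lag: float = 1.0,
                pi: np.ndarray | None = None) -> float:
    """Exact set-to-set MFPT of an arbitrary Markov chain, in lag-time units.

    Same aggregation as :func:`mfpt` — microstate first-passage times to the
    target set, stationary-weighted over the source set — but computed
    directly from a raw transition matrix. Used as the ground-truth value
    for planted chains.
    """
    T = np.asarray(transition_matrix, dtype=float)
    n = T.shape[0]
    source = np.asarray(source, dtype=int)
    target = np.asarray(target, dtype=int)
    if pi is None:
        w, v = np.linalg.eig(T.T)
        pi = np.abs(v[:, int(np.argmax(w.real))].real)
        pi = pi / pi.sum()
    m = np.zeros(n)
    rest = np.setdiff1d(np.arange(n), target)
    A = np.eye(rest.size) - T[np.ix_(rest, rest)]
    m[rest] = np.linalg.solve(A, np.full(rest.size, lag))
    wts = pi[source] / pi[source].sum()
    return float(wts @ m[source])


def mfpt_to_set(model: MSMModel, target: np.ndarray) -> np.ndarray:
    """Mean first passage time (ns) from every microstate to a target set.

    Solves (I - T_rest) m = tau 1 on the non-target states with the target
    rows absorbing (m = 0 there).
    """
    T = model.transition_matrix
    n = T.shape[0]
    target = np.asarray(target, dtype=int)
    if target.size == 0:
        raise ValueError("target set is empty")
    m = np.zeros(n)
    rest = np.setdiff1d(np.arange(n), target)
    if rest.size:
        A = np.eye(rest.size) - T[np.ix_(rest, rest)]
        try:
            m[rest] = np.linalg.solve(A, np.full(rest.size, model.lag_ns))
        except np.linalg.LinAlgError as exc:
            raise ValueError("target set unreachable from part of the chain") from exc
        if np.any(m < -1e-9) or not np.all(np.isfinite(m)):
            raise ValueError("target set unreachable: MFPT is infinite")
    return m


def mfpt(model: MSMModel, macro: MacrostateModel, source: int, target: int) -> float:
    """Macrostate-to-macrostate mean first passage time in ns.

    Stationary-weighted average of microstate MFPTs over the source's crisp
    set; zero when source equals target.
    """
    if source == target:
        return 0.0
    sets = macro.crisp_sets()
    src, tgt = sets[source], sets[target]
    if src.size == 0 or tgt.size == 0:
        raise ValueError("source and target macrostates must be non-empty")
    m = mfpt_to_set(model, tgt)
    pi = model.stationary_distribution
    w = pi[src] / pi[src].sum()
    return float(w @ m[src])


def mfpt_matrix(model: MSMModel, macro: MacrostateModel) -> np.ndarray:
    """All pairwise macrostate MFPTs (ns); zero diagonal."""
    n = macro.n_macrostates
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                M[i, j] = mfpt(model, macro, i, j)
    return M


@dataclass
class KineticsResult:
    """Committors, reactive fluxes and the A->B rate on the microstate model."""

    source_set: np.ndarray
    target_set: np.ndarray
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    rate_per_ns: float


def committor_and_flux(model: MSMModel, A: np.ndarray, B: np.ndarray) -> KineticsResult:
    """Transition path theory between microstate sets A and B.

    q+ solves the committor system (0 on A, 1 on B, harmonic elsewhere);
    for a reversible chain q- = 1 - q+. Gross reactive flux
    f_ij = pi_i q-_i T_ij q+_j (i != j), net flux its positive antisymmetric
    part, and the A->B rate the total reactive flux out of A divided by
    tau * sum_i pi_i q-_i.
    """
    A = np.asarray(A, dtype=int)
    B = np.asarray(B, dtype=int)
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B overlap")
    T = model.transition_matrix
    n = T.shape[0]
    qp = np.zeros(n)
    qp[B] = 1.0
    C = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if C.size:
        M = np.eye(C.size) - T[np.ix_(C, C)]
        rhs = T[np.ix_(C, B)].sum(axis=1)
        qp[C] = np.linalg.solve(M, rhs)
    qm = 1.0 - qp   # reversible chain

    pi = model.stationary_distribution
    gross = (pi * qm)[:, None] * T * qp[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.clip(gross - gross.T, 0.0, None)
    reactive_out = net[A].sum() - net[np.ix_(A, A)].sum()
    denom = model.lag_ns * float(pi @ qm)
    rate = float(reactive_out / denom) if denom > 0 else np.inf
    return KineticsResult(
        source_set=A, target_set=B, forward_committor=qp, backward_committor=qm,
        gross_flux=gross, net_flux=net, rate_per_ns=rate,
    )


def coarse_transition_network(model: MSMModel, macro: MacrostateModel) -> pd.DataFrame:
    """Macrostate-level transition probabilities at lag tau, as an edge list.

    P_IJ = sum_{i in I, j in J} pi_i T_ij / pi(I) over crisp sets; node
    weights are the macrostate stationary probabilities. Rows of the coarse
    matrix sum to 1.
    """
    pi = model.stationary_distribution
    T = model.transition_matrix
    sets = macro.crisp_sets()
    rows = []
    for I, Si in enumerate(sets):
        pI = pi[Si].sum()
        for J, Sj in enumerate(sets):
            flux = float(pi[Si] @ T[np.ix_(Si, Sj)].sum(axis=1))
            rows.append({
                "source": I, "target": J,
                "probability": flux / pI if pI > 0 else np.nan,
                "source_weight": pI, "target_weight": pi[Sj].sum(),
            })
    return pd.DataFrame(rows)
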