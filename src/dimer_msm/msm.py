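"""Microstate discretization and reversible Markov state model estimation.

The pipeline stage covered here: k-means discretization of the TICA-projected
trajectories into microstates, sliding-window transition counting at a lag
tau restricted to the largest strongly connected component, maximum-likelihood
estimation of a reversible (detailed-balance) transition matrix T with its
stationary distribution pi, implied-timescale and Chapman-Kolmogorov
diagnostics, and stationary free energies of state groups,

    dG(S_i) = -k_B T ln sum_{j in S_i} pi_j   [kJ/mol].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Molar gas constant in kJ/(mol K); k_B T per mole at temperature T.
GAS_CONSTANT_KJ_PER_MOL_K = 8.314462618e-3


@dataclass
class Discretization:
    """k-means microstate assignment of projected trajectories."""

    centers: np.ndarray
    labels: list[np.ndarray]
    seed: int
    inertia: float

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]


@dataclass
class MSMModel:
    """Reversible MSM on the largest connected set of microstates.

    ``active_set`` maps the rows of ``transition_matrix`` back to the original
    microstate indices; ``counts`` is the raw (unrestricted) count matrix.
    """

    lag_frames: int
    lag_ns: float
    counts: np.ndarray
    active_set: np.ndarray
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    n_iterations: int
    converged: bool
    coverage: float = 1.0   # fraction of counted frames inside the active set

    @property
    def n_states(self) -> int:
        return len(self.active_set)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real sorted (descending) eigenvalues via the reversible symmetrization."""
        lam, _ = _reversible_eigh(self.transition_matrix, self.stationary_distribution)
        return lam if k is None else lam[:k]

    def timescales_ns(self, k: int | None = None) -> np.ndarray:
        """Implied timescales -tau/ln(lambda_i) for i >= 2, in ns."""
        lam = self.eigenvalues(None if k is None else k + 1)[1:]
        out = np.full(lam.shape, np.nan)
        pos = lam > 0
        out[pos] = -self.lag_ns / np.log(lam[pos])
        if np.any(~pos):
            logger.warning("%d eigenvalues <= 0; their timescales are undefined",
                           int((~pos).sum()))
        return out


@dataclass
class CKResult:
    """Chapman-Kolmogorov test: predicted vs re-estimated residence probabilities."""

    factors: list[int]
    predicted: np.ndarray     # (n_factors, n_sets)
    estimated: np.ndarray     # (n_factors, n_sets)
    error: np.ndarray         # (n_factors, n_sets) one-sigma bands on estimated

    def max_deviation(self) -> float:
        return float(np.max(np.abs(self.predicted - self.estimated)))


def cluster_microstates(projected: list[np.ndarray], k: int, seed: int = 0,
                        max_iter: int = 300, tol: float = 1e-6) -> Discretization:
    """Discretize projected trajectories into k microstates with k-means.

    k-means++ initialization from ``seed``, Lloyd iterations to ``tol`` or
    ``max_iter``; frames are labelled by their nearest center (Euclidean).
    """
    X = np.concatenate(projected, axis=0)
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of frames ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                tol=tol, random_state=seed)
    km.fit(X)
    labels = []
    start = 0
    for traj in projected:
        labels.append(km.labels_[start:start + traj.shape[0]].astype(np.int64))
        start += traj.shape[0]
    return Discretization(centers=km.cluster_centers_, labels=labels, seed=seed,
                          inertia=float(km.inertia_))


def count_transitions(labels: list[np.ndarray], lag_frames: int,
                      n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts pooled over replicas.

    C_ij counts frame pairs (t, t+lag) within one replica; windows never
    cross replica boundaries.
    """
    if n_states is None:
        n_states = int(max(seq.max() for seq in labels)) + 1
    C = np.zeros((n_states, n_states))
    for seq in labels:
        seq = np.asarray(seq)
        if len(seq) <= lag_frames:
            raise ValueError(
                f"replica of {len(seq)} frames is not longer than the lag "
                f"({lag_frames} frames)"
            )
        np.add.at(C, (seq[:-lag_frames], seq[lag_frames:]), 1.0)
    return C


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph."""
    n_comp, assignment = connected_components(counts > 0, directed=True,
                                              connection="strong")
    sizes = np.bincount(assignment, minlength=n_comp)
    # among equally sized components prefer the one with the most counts
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(assignment == comp)
        key = (sizes[comp], counts[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None or counts[np.ix_(best, best)].sum() == 0:
        raise ValueError("empty active set: no connected transitions observed")
    return best


def count_and_connect(labels: list[np.ndarray], lag: float, frame_interval: float,
                      n_states: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Counts at a physical lag (ns) plus the largest connected active set."""
    from .tica import lag_to_frames

    lag_frames = lag_to_frames(lag, frame_interval)
    C = count_transitions(labels, lag_frames, n_states)
    return C, largest_connected_set(C)


def estimate_reversible_transition_matrix(
        counts: np.ndarray, lag_frames: int = 1, lag_ns: float = 1.0,
        active_set: np.ndarray | None = None, tol: float = 1e-10,
        max_iter: int = 1_000_000, coverage: float = 1.0) -> MSMModel:
    """Maximum-likelihood reversible transition matrix from transition counts.

    Self-consistent iteration on the symmetric unnormalized flow x_ij = x_ji:

        x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j),

    with c_i the count row sums and x_i = sum_j x_ij; at the fixed point
    T_ij = x_ij / x_i maximizes the likelihood under detailed balance and
    pi_i = x_i / sum(x). Iterates until the maximum relative change in x
    falls below ``tol``.
    """
    counts = np.asarray(counts, dtype=float)
    if active_set is None:
        active_set = largest_connected_set(counts)
    C = counts[np.ix_(active_set, active_set)]
    n = C.shape[0]
    c_row = C.sum(axis=1)
    if np.any(c_row == 0):
        raise ValueError("active set contains states with no outgoing counts")
    sym = C + C.T
    x = sym / sym.sum()         # symmetric start
    x_row = x.sum(axis=1)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        denom = c_row / x_row
        x_new = sym / (denom[:, None] + denom[None, :])
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x) / np.maximum(x, 1e-300))
        x = x_new
        x_row = x.sum(axis=1)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"reversible estimator did not converge in {max_iter} sweeps "
            f"(last relative change {delta:.2e})"
        )
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    # guard: pi must also be the leading left eigenvector
    resid = np.max(np.abs(pi @ T - pi))
    if resid > 1e-8:
        raise RuntimeError(f"stationary distribution residual {resid:.2e} > 1e-8")
    return MSMModel(
        lag_frames=lag_frames, lag_ns=lag_ns, counts=counts,
        active_set=np.asarray(active_set), transition_matrix=T,
        stationary_distribution=pi, n_iterations=n_iter, converged=converged,
        coverage=coverage,
    )


def estimate_msm(labels: list[np.ndarray], lag: float, frame_interval: float,
                 n_states: int | None = None) -> MSMModel:
    """Counts -> largest connected set -> reversible MLE, at a physical lag."""
    from .tica import lag_to_frames

    lag_frames = lag_to_frames(lag, frame_interval)
    C = count_transitions(labels, lag_frames, n_states)
    active = largest_connected_set(C)
    coverage = float(C[np.ix_(active, active)].sum() / C.sum())
    if coverage < 1.0:
        logger.info("active set covers %.4f of counted transitions", coverage)
    return estimate_reversible_transition_matrix(
        C, lag_frames=lag_frames, lag_ns=lag_frames * frame_interval,
        active_set=active, coverage=coverage)


def _reversible_eigh(T: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition via the pi-symmetrized similarity transform.

    Returns real eigenvalues (descending) and RIGHT eigenvectors of T.
    """
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    lam, u = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    right = u / sqrt_pi[:, None]
    # normalize sign and pi-norm; first vector becomes the constant 1
    for j in range(right.shape[1]):
        norm = np.sqrt(np.sum(pi * right[:, j] ** 2))
        right[:, j] /= norm
        if right[np.argmax(np.abs(right[:, j])), j] < 0:
            right[:, j] *= -1
    return lam, right


def implied_timescales(labels: list[np.ndarray], lags: list[float],
                       frame_interval: float, n_timescales: int = 5,
                       n_states: int | None = None) -> "np.ndarray":
    """Implied timescales t_i = -tau/ln(lambda_i) across candidate lags.

    Returns an (n_lags, n_timescales) array in ns; undefined timescales
    (nonpositive eigenvalues) are NaN.
    """
    rows = []
    for lag in lags:
        model = estimate_msm(labels, lag, frame_interval, n_states)
        ts = model.timescales_ns(k=n_timescales)
        if len(ts) < n_timescales:
            ts = np.concatenate([ts, np.full(n_timescales - len(ts), np.nan)])
        rows.append(ts[:n_timescales])
    return np.asarray(rows)


def ck_test(model: MSMModel, labels: list[np.ndarray], macrosets: list[np.ndarray],
            factors: list[int], frame_interval: float) -> CKResult:
    """Chapman-Kolmogorov test over groups of microstates.

    Predicted residence probability of set I after k tau: propagate the
    model, P_pred(k)_I = sum_{i in I} pi_i [T^k 1_I]_i / pi(I). Estimated:
    the same quantity from a model re-estimated at lag k tau. Bands are the
    binomial normal approximation sqrt(p(1-p)/N_I) with N_I the number of
    transition pairs leaving set I at lag k tau.
    """
    for k in factors:
        if k < 1:
            raise ValueError("CK factors must be >= 1")
    sets = [np.asarray(s) for s in macrosets]
    covered = np.sort(np.concatenate(sets))
    if not np.array_equal(covered, np.sort(model.active_set)):
        raise ValueError("macrosets must partition the active set")
    index_of = {s: i for i, s in enumerate(model.active_set)}
    local_sets = [np.asarray([index_of[s] for s in S]) for S in sets]

    pi = model.stationary_distribution
    T = model.transition_matrix
    max_len = max(len(seq) for seq in labels)
    usable = []
    for k in sorted(factors):
        if k * model.lag_frames >= max_len:
            logger.warning("CK factor %d exceeds replica length; dropped", k)
            continue
        usable.append(k)
    predicted_rows, estimated_rows, error_rows = [], [], []
    for k in usable:
        Tk = np.linalg.matrix_power(T, k)
        pred = []
        for Sloc in local_sets:
            w = pi[Sloc] / pi[Sloc].sum()
            pred.append(float(w @ Tk[np.ix_(Sloc, Sloc)].sum(axis=1)))
        model_k = estimate_msm(labels, k * model.lag_ns, frame_interval,
                               n_states=model.counts.shape[0])
        idx_k = {s: i for i, s in enumerate(model_k.active_set)}
        est, err = [], []
        Ck = model_k.counts
        for S in sets:
            members = [s for s in S if s in idx_k]
            if not members:
                est.append(np.nan)
                err.append(np.nan)
                continue
            loc = np.asarray([idx_k[s] for s in members])
            pik = model_k.stationary_distribution
            w = pik[loc] / pik[loc].sum()
            Tkk = model_k.transition_matrix
            p = float(w @ Tkk[np.ix_(loc, loc)].sum(axis=1))
            n_obs = Ck[np.asarray(members)].sum()
            est.append(p)
            err.append(np.sqrt(max(p * (1 - p), 0.0) / max(n_obs, 1.0)))
        predicted_rows.append(pred)
        estimated_rows.append(est)
        error_rows.append(err)
    return CKResult(
        factors=usable,
        predicted=np.asarray(predicted_rows),
        estimated=np.asarray(estimated_rows),
        error=np.asarray(error_rows),
    )


def macrostate_free_energies(pi: np.ndarray, assignment: np.ndarray,
                             temperature: float = 310.0) -> np.ndarray:
    """Stationary free energy per macrostate, dG = -k_B T ln(sum pi), kJ/mol.

    ``assignment`` maps each microstate to a macrostate index; empty
    macrostates get +inf. Values are absolute in the sense that the full
    ensemble has dG = 0; differences between macrostates are what carry
    physical meaning.
    """
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("stationary distribution must be normalized")
    assignment = np.asarray(assignment, dtype=int)
    if len(assignment) != len(pi):
        raise ValueError("assignment must cover every microstate")
    n_macro = assignment.max() + 1
    kt = GAS_CONSTANT_KJ_PER_MOL_K * temperature
    dg = np.full(n_macro, np.inf)
    for macro in range(n_macro):
        weight = pi[assignment == macro].sum()
        if weight > 0:
            dg[macro] = -kt * np.log(weight)
        else:
            logger.warning("macrostate %d is empty; free energy undefined", macro)
    return dg
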