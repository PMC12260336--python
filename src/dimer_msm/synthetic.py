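"""Synthetic trajectory generators with known ground-truth kinetics.

Two generators stand in for long coarse-grained MD of a reversibly
associating two-chain protein:

* exact discrete Markov-jump chains with state-conditional Gaussian distance
  emissions — every downstream estimator can be checked against the planted
  transition matrix;
* a toy overdamped Langevin simulation of two rigid two-domain bodies in a
  reflecting box with a short-range attractive well — a continuous-space
  emulation of reversible binding/unbinding with a tunable well depth.

Units are nm and ns throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurization import FeatureMatrix
from .trajectory import Topology, TrajectoryEnsemble, write_manifest


@dataclass
class GroundTruthChain:
    """A reversible-jump ground truth: transition matrix plus emission model.

    Parameters
    ----------
    transition_matrix : (n, n) array
        Row-stochastic transition probabilities per lag step.
    lag_step : float
        Physical time per jump, ns.
    emission_means : (n, 4) array
        Mean inter-domain COM distances (nm) emitted in each state, in the
        documented feature column order.
    emission_sd : float
        Shared Gaussian emission width (nm), truncated at zero.
    state_labels : sequence of str
        ``"bound"`` or ``"unbound"`` per state.
    """

    transition_matrix: np.ndarray
    lag_step: float
    emission_means: np.ndarray
    emission_sd: float
    state_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition matrix has negative entries")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
        self.transition_matrix = T
        means = np.atleast_2d(np.asarray(self.emission_means, dtype=float))
        if means.shape[0] != T.shape[0]:
            raise ValueError("one emission mean vector required per state")
        self.emission_means = means
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive (ns)")
        self.state_labels = tuple(self.state_labels)
        if len(self.state_labels) != T.shape[0]:
            raise ValueError("one bound/unbound label required per state")
        bad = set(self.state_labels) - {"bound", "unbound"}
        if bad:
            raise ValueError(f"state labels must be bound/unbound, got {sorted(bad)}")
        if np.any(np.isclose(np.diag(T), 1.0)):
            warnings.warn(
                "chain has an absorbing state; first-passage times to other "
                "states are undefined", stacklevel=2,
            )

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Leading left eigenvector of the transition matrix, normalized."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmax(w.real))
        pi = np.abs(v[:, i].real)
        return pi / pi.sum()

    def bound_states(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.state_labels, object) == "bound")

    def unbound_states(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.state_labels, object) == "unbound")


def association_chain(emission_sd: float = 0.35, lag_step: float = 1.0) -> GroundTruthChain:
    """The package's default 6-state reversible association ground truth.

    Two unbound states (monomer-like emissions above 7 nm, state 1 acting as
    the encounter gateway) and a four-state bound basin with distinct
    inter-domain distance signatures below 6 nm. Built from a symmetric
    weight matrix, so detailed balance holds exactly. The basin depths are
    chosen to plant a ~24-fold asymmetry between the dissociation MFPT
    (~1017 lag steps) and the association MFPT (~42 steps), i.e. a system
    that binds fast and unbinds slowly.
    """
    W = np.zeros((6, 6))
    W[0, 1] = W[1, 0] = 0.5          # unbound mixing
    W[1, 2] = W[2, 1] = 0.05         # association gateway
    for i, j in [(2, 3), (3, 4), (4, 5), (2, 4), (3, 5)]:
        W[i, j] = W[j, i] = 1.0      # bound-basin mixing
    W[0, 0] = W[1, 1] = 0.5
    for i in range(2, 6):
        W[i, i] = 10.0               # deep bound basin
    T = W / W.sum(axis=1, keepdims=True)
    means = np.array([
        [9.0, 9.2, 9.2, 9.0],        # dissociated
        [8.0, 8.2, 8.2, 8.0],        # encounter, still monomeric
        [5.5, 5.0, 5.0, 5.5],        # early dimer
        [3.5, 5.0, 5.0, 3.5],
        [5.0, 3.0, 3.0, 5.0],
        [3.0, 3.5, 3.5, 3.0],        # compact late dimer
    ])
    labels = ("unbound", "unbound", "bound", "bound", "bound", "bound")
    return GroundTruthChain(T, lag_step, means, emission_sd, labels)


def simulate_markov_chain(chain: GroundTruthChain, n_steps: int, n_replicas: int,
                          seed: int, start_unbound: bool = False) -> list[np.ndarray]:
    """Sample discrete state trajectories from the ground-truth chain.

    Initial states are drawn from the stationary distribution so that
    empirical occupancies are stationary from the first frame; with
    ``start_unbound=True`` every replica instead starts in a random unbound
    state, mimicking a dissociated initial condition.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if n_replicas < 1:
        raise ValueError("n_replicas must be at least 1")
    rng = np.random.default_rng(seed)
    pi = chain.stationary_distribution()
    if start_unbound:
        unbound = chain.unbound_states()
        if unbound.size == 0:
            raise ValueError("start_unbound requires at least one unbound state")
        w = pi[unbound] / pi[unbound].sum()
        states = rng.choice(unbound, size=n_replicas, p=w)
    else:
        states = rng.choice(chain.n_states, size=n_replicas, p=pi)

    cum = np.cumsum(chain.transition_matrix, axis=1)
    labels = np.empty((n_replicas, n_steps), dtype=np.int64)
    labels[:, 0] = states
    u = rng.random((n_steps - 1, n_replicas))
    for t in range(1, n_steps):
        rows = cum[labels[:, t - 1]]
        labels[:, t] = (u[t - 1][:, None] > rows).sum(axis=1)
    return [labels[r] for r in range(n_replicas)]


def emit_distance_trajectories(labels: list[np.ndarray], chain: GroundTruthChain,
                               seed: int) -> FeatureMatrix:
    """Emit per-frame distance observations conditioned on the hidden state.

    Each frame draws Normal(emission_means[state], emission_sd) per feature,
    truncated at zero (distances are nonnegative).
    """
    rng = np.random.default_rng(seed)
    out = []
    for r, seq in enumerate(labels):
        seq = np.asarray(seq)
        if np.any(seq < 0) or np.any(seq >= chain.n_states):
            bad = int(np.flatnonzero((seq < 0) | (seq >= chain.n_states))[0])
            raise IndexError(
                f"replica {r}, frame {bad}: state {seq[bad]} outside "
                f"0..{chain.n_states - 1}"
            )
        X = chain.emission_means[seq] + rng.normal(
            0.0, chain.emission_sd, size=(len(seq), chain.emission_means.shape[1]))
        out.append(np.maximum(X, 0.0))
    return FeatureMatrix(replicas=out, frame_interval=chain.lag_step)


@dataclass
class LangevinParams:
    """Settings for the toy two-body dimerization simulation.

    ``well_depth`` is in units of kT; ``contact_radius`` is the COM
    separation below which the flat-bottom attractive well applies, with a
    linear ramp of width ``ramp_width`` back to zero. The box is a cube of
    half-width ``box_half_width`` with reflecting walls acting on body COMs.
    """

    well_depth: float = 4.0
    contact_radius: float = 1.5
    box_half_width: float = 5.0
    diffusion_coeff: float = 0.5
    dt: float = 0.02
    n_steps: int = 50_000
    n_replicas: int = 1
    beads_per_domain: int = 2
    seed: int = 0
    ramp_width: float = 0.5
    initial_separation: float = 8.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive (ns)")
        if self.contact_radius >= self.box_half_width:
            raise ValueError("contact_radius must be smaller than box_half_width")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be at least 1")
        if self.well_depth < 0:
            raise ValueError("well_depth must be nonnegative (kT)")
        if self.ramp_width <= 0:
            raise ValueError("ramp_width must be positive (nm)")
        if self.beads_per_domain < 1:
            raise ValueError("beads_per_domain must be at least 1")


def _body_offsets(beads_per_domain: int) -> tuple[np.ndarray, Topology]:
    """Fixed internal geometry of one rigid two-domain body, and the dimer topology.

    Each body is two small bead clusters (Ntd, Ctd) 1 nm apart along z.
    Returns per-bead offsets for ONE body and the topology of the two-body
    system (chain A beads first).
    """
    per_dom = beads_per_domain
    offs = []
    for d, z0 in enumerate((-0.5, 0.5)):       # Ntd at -0.5, Ctd at +0.5
        for b in range(per_dom):
            # spread beads slightly along x so multi-bead COMs are nontrivial
            offs.append([0.1 * (b - (per_dom - 1) / 2), 0.0, z0])
    offs = np.asarray(offs)
    n_body = len(offs)
    chains = np.array(["A"] * n_body + ["B"] * n_body, dtype=object)
    domains = np.array((["Ntd"] * per_dom + ["Ctd"] * per_dom) * 2, dtype=object)
    top = Topology(chain_ids=chains, domain_ids=domains,
                   masses=np.ones(2 * n_body),
                   residue_ids=np.arange(2 * n_body))
    return offs, top


def pair_potential(r: np.ndarray | float, params: LangevinParams) -> np.ndarray:
    """Flat-bottom well in kT: -depth inside contact_radius, linear ramp to 0."""
    r = np.asarray(r, dtype=float)
    rc, w, depth = params.contact_radius, params.ramp_width, params.well_depth
    u = np.where(r < rc, -depth,
                 np.where(r < rc + w, -depth * (rc + w - r) / w, 0.0))
    return u


def _pair_force_magnitude(r: float, params: LangevinParams) -> float:
    """-dU/dr in kT/nm (positive = attractive toward contact)."""
    rc, w, depth = params.contact_radius, params.ramp_width, params.well_depth
    if rc < r < rc + w:
        return -depth / w
    return 0.0


def simulate_langevin_dimerization(params: LangevinParams) -> TrajectoryEnsemble:
    """Overdamped Euler-Maruyama dynamics of two rigid two-domain bodies.

    Bodies diffuse translationally (no internal or rotational dynamics) in a
    reflecting cubic box; an attractive flat-bottom well acts on their COM
    separation. Replicas start with COMs separated by
    ``params.initial_separation`` (clipped to fit the box) along x.
    """
    offs, top = _body_offsets(params.beads_per_domain)
    rng = np.random.default_rng(params.seed)
    L = params.box_half_width
    D = params.diffusion_coeff
    dt = params.dt
    sqrt2Ddt = np.sqrt(2.0 * D * dt)

    half_sep = min(params.initial_separation / 2.0, 0.9 * L)
    # positions: (replica, body, 3)
    pos = np.zeros((params.n_replicas, 2, 3))
    pos[:, 0, 0] = -half_sep
    pos[:, 1, 0] = +half_sep

    frames = np.empty((params.n_replicas, params.n_steps, 2, 3))
    for t in range(params.n_steps):
        frames[:, t] = pos
        dvec = pos[:, 1] - pos[:, 0]
        r = np.linalg.norm(dvec, axis=1)
        fmag = np.array([_pair_force_magnitude(ri, params) for ri in r])
        # unit vector body0 -> body1; attractive force pulls them together
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, dvec / np.maximum(r, 1e-12)[:, None], 0.0)
        drift = D * dt * fmag[:, None] * unit        # kT-reduced force * D/kT
        noise = sqrt2Ddt * rng.standard_normal(pos.shape)
        step0 = -drift + noise[:, 0]
        step1 = +drift + noise[:, 1]
        max_step = max(np.abs(step0).max(initial=0), np.abs(step1).max(initial=0))
        if max_step > 2 * L:
            raise FloatingPointError(
                f"step displacement {max_step:.2f} nm exceeds box size at t={t}; "
                "reduce dt"
            )
        pos = pos + np.stack([step0, step1], axis=1)
        # reflecting walls on body COMs
        pos = np.where(pos > L, 2 * L - pos, pos)
        pos = np.where(pos < -L, -2 * L - pos, pos)

    replicas = [frames[rep][:, :, None, :] + offs[None, None, :, :]
                for rep in range(params.n_replicas)]
    replicas = [r.reshape(params.n_steps, 2 * len(offs), 3) for r in replicas]
    return TrajectoryEnsemble(replicas=replicas, frame_interval=dt, topology=top)


def write_simulation_manifest(path: str | Path, params: LangevinParams) -> Path:
    """Record the replica plan, seed and parameters alongside written output."""
    return write_manifest(
        path,
        generator="langevin_dimerization",
        seed=params.seed,
        n_replicas=params.n_replicas,
        n_steps=params.n_steps,
        frame_interval_ns=params.dt,
        well_depth_kT=params.well_depth,
        contact_radius_nm=params.contact_radius,
        box_half_width_nm=params.box_half_width,
        diffusion_coeff_nm2_per_ns=params.diffusion_coeff,
        beads_per_domain=params.beads_per_domain,
        initial_separation_nm=params.initial_separation,
    )
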