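"""Shared fixtures: small ground-truth chains and toy dimer ensembles."""

import numpy as np
import pytest

from dimer_msm import GroundTruthChain, Topology, TrajectoryEnsemble


@pytest.fixture
def two_state_chain() -> GroundTruthChain:
    """Asymmetric 2-state chain with bound/unbound emissions."""
    T = np.array([[0.9, 0.1], [0.5, 0.5]])
    means = np.array([[4.0, 4.5, 4.5, 4.0], [8.5, 9.0, 9.0, 8.5]])
    return GroundTruthChain(T, lag_step=1.0, emission_means=means,
                            emission_sd=0.3, state_labels=("bound", "unbound"))


@pytest.fixture
def reversible_three_state() -> np.ndarray:
    """Reversible 3-state transition matrix built from symmetric weights."""
    W = np.array([[4.0, 1.0, 0.5],
                  [1.0, 6.0, 1.5],
                  [0.5, 1.5, 3.0]])
    return W / W.sum(axis=1, keepdims=True)


def make_toy_ensemble(frames: list[np.ndarray], frame_interval: float = 1.0,
                      masses: np.ndarray | None = None) -> TrajectoryEnsemble:
    """Four-bead dimer (one bead per domain per chain) from explicit frames."""
    n = frames[0].shape[1]
    per_chain = n // 2
    per_dom = per_chain // 2
    top = Topology(
        chain_ids=np.array(["A"] * per_chain + ["B"] * per_chain, dtype=object),
        domain_ids=np.array((["Ntd"] * per_dom + ["Ctd"] * per_dom) * 2,
                            dtype=object),
        masses=np.ones(n) if masses is None else masses,
    )
    return TrajectoryEnsemble(replicas=frames, frame_interval=frame_interval,
                              topology=top)


@pytest.fixture
def four_bead_ensemble() -> TrajectoryEnsemble:
    """A.Ntd at origin, A.Ctd at (0,0,1), B mirrored at x=3: one static frame."""
    frame = np.array([[[0.0, 0.0, 0.0],
                       [0.0, 0.0, 1.0],
                       [3.0, 0.0, 0.0],
                       [3.0, 0.0, 1.0]]])
    return make_toy_ensemble([frame])
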