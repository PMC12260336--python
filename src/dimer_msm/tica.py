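"""Time-lagged independent component analysis (TICA).

TICA finds linear combinations of input features that decorrelate most
slowly: with C0 the instantaneous covariance and C_tau the time-lagged
covariance of mean-free features, it solves the generalized eigenproblem

    C_tau v = lambda C0 v.

The estimator here is the symmetrized (reversible) one: statistics are
accumulated over the frame pairs (x_t, x_{t+tau}) of every replica with both
ends of each pair contributing to the mean and to C0, and C_tau is averaged
with its transpose. This guarantees real eigenvalues and makes the fit
invariant under time reversal of the data.

The kinetic variance of component i is defined spectrally as
lambda_i^2 / sum_j lambda_j^2; components are kept until their cumulative
kinetic variance reaches the requested fraction (95% in the standard
configuration of this package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .featurization import FeatureMatrix

logger = logging.getLogger(__name__)

#: Relative eigenvalue floor below which C0 directions are treated as degenerate.
C0_EIGENVALUE_FLOOR = 1e-10


@dataclass
class TICAModel:
    """Fitted TICA transform.

    ``eigenvectors`` columns are the independent components in feature space
    (all solved components, not only the kept ones); projection uses the
    first ``n_components_kept`` columns.
    """

    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lag_frames: int
    frame_interval: float
    kinetic_variance_fractions: np.ndarray
    n_components_kept: int

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.frame_interval

    def timescales_ns(self) -> np.ndarray:
        """Implied relaxation timescales -tau/ln|lambda| per component (ns)."""
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            return np.where((lam > 0) & (lam < 1), -self.lag_ns / np.log(lam), np.inf)

    def save(self, path: str | Path) -> Path:
        np.savez(
            Path(path), mean=self.mean, c0=self.c0, ctau=self.ctau,
            eigenvalues=self.eigenvalues, eigenvectors=self.eigenvectors,
            lag_frames=self.lag_frames, frame_interval=self.frame_interval,
            kinetic_variance_fractions=self.kinetic_variance_fractions,
            n_components_kept=self.n_components_kept,
        )
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "TICAModel":
        with np.load(Path(path)) as d:
            return cls(
                mean=d["mean"], c0=d["c0"], ctau=d["ctau"],
                eigenvalues=d["eigenvalues"], eigenvectors=d["eigenvectors"],
                lag_frames=int(d["lag_frames"]),
                frame_interval=float(d["frame_interval"]),
                kinetic_variance_fractions=d["kinetic_variance_fractions"],
                n_components_kept=int(d["n_components_kept"]),
            )


def lag_to_frames(lag_ns: float, frame_interval: float) -> int:
    """Convert a physical lag to frames, rounding to the nearest frame."""
    frames = int(round(lag_ns / frame_interval))
    if not np.isclose(frames * frame_interval, lag_ns):
        logger.warning(
            "lag %.3f ns is not a multiple of the frame interval %.3f ns; "
            "rounded to %d frames (%.3f ns)",
            lag_ns, frame_interval, frames, frames * frame_interval,
        )
    if frames < 1:
        raise ValueError(
            f"lag {lag_ns} ns is below one frame interval ({frame_interval} ns)")
    return frames


def _pair_statistics(replicas: list[np.ndarray], lag_frames: int):
    """Symmetrized mean, C0 and C_tau over all (x_t, x_{t+tau}) pairs."""
    d = replicas[0].shape[1]
    n_pairs = 0
    s = np.zeros(d)
    for X in replicas:
        if X.shape[0] <= lag_frames:
            raise ValueError(
                f"replica of {X.shape[0]} frames is not longer than the lag "
                f"({lag_frames} frames)"
            )
        head, tail = X[:-lag_frames], X[lag_frames:]
        s += head.sum(axis=0) + tail.sum(axis=0)
        n_pairs += head.shape[0]
    mean = s / (2 * n_pairs)

    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    for X in replicas:
        head = X[:-lag_frames] - mean
        tail = X[lag_frames:] - mean
        c0 += head.T @ head + tail.T @ tail
        ctau += head.T @ tail
    c0 /= 2 * n_pairs
    ctau /= n_pairs
    ctau = 0.5 * (ctau + ctau.T)
    return mean, c0, ctau


def fit_tica(features: FeatureMatrix, lag: float,
             variance_cutoff: float = 0.95) -> TICAModel:
    """Fit TICA at a physical lag (ns), keeping the requested kinetic variance.

    C0 directions whose eigenvalue falls below ``C0_EIGENVALUE_FLOOR`` times
    the largest are discarded (degenerate features) before the whitened
    symmetric eigenproblem is solved.
    """
    if not (0 < variance_cutoff <= 1):
        raise ValueError("variance_cutoff must lie in (0, 1]")
    lag_frames = lag_to_frames(lag, features.frame_interval)
    mean, c0, ctau = _pair_statistics(features.replicas, lag_frames)

    # regularized whitening of C0
    evals, evecs = np.linalg.eigh(c0)
    keep = evals > C0_EIGENVALUE_FLOOR * evals.max()
    if not np.all(keep):
        logger.warning("C0 is rank-deficient: discarding %d of %d directions",
                       int((~keep).sum()), len(keep))
    evals, evecs = evals[keep], evecs[:, keep]
    whiten = evecs / np.sqrt(evals)                     # d x m
    m = whiten.shape[1]

    sym = whiten.T @ ctau @ whiten                      # m x m, symmetric
    sym = 0.5 * (sym + sym.T)
    lam, u = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]                       # descending by value
    lam, u = lam[order], u[:, order]
    vectors = whiten @ u                                # generalized eigenvectors

    kin = lam ** 2
    cum = np.cumsum(kin) / kin.sum()
    n_keep = int(np.searchsorted(cum, variance_cutoff - 1e-12) + 1)
    n_keep = min(n_keep, m)
    return TICAModel(
        mean=mean, c0=c0, ctau=ctau, eigenvalues=lam, eigenvectors=vectors,
        lag_frames=lag_frames, frame_interval=features.frame_interval,
        kinetic_variance_fractions=cum, n_components_kept=n_keep,
    )


def project(model: TICAModel, features: FeatureMatrix) -> list[np.ndarray]:
    """Project features onto the kept independent components, per replica."""
    V = model.eigenvectors[:, : model.n_components_kept]
    out = []
    for X in features.replicas:
        if X.shape[1] != model.mean.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the model "
                f"({model.mean.shape[0]})"
            )
        out.append((X - model.mean) @ V)
    return out
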