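"""Rigid-body superposition and per-residue fluctuation profiles.

The central operation is the sliding-window profile: short overlapping
segments (10 residues by default) are superposed independently, so that
whole-body rotations and translations cancel and only internal backbone
flexibility remains. A whole-chain (global) superposition profile is kept
for comparison; on chains with a rigid core and mobile tails it inflates
the apparent fluctuation of the core, which is exactly the artefact the
windowed profile avoids.

Fluctuations are measured against an iteratively refined mean structure:
all models are superposed on the current mean, the mean is recomputed, and
the loop repeats until the mean stops moving. The per-residue value is the
root-mean-square deviation of that residue from the mean position across
models (an RMSF in the usual molecular-dynamics sense).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CoordinateEnsemble, FlexibilityProfile, RigidTransform

__all__ = [
    "WindowSpec",
    "kabsch",
    "pairwise_rmsd",
    "window_profile",
    "global_profile",
]

_MEAN_TOL = 1e-6  # angstrom; convergence of the iterative mean structure
_MEAN_MAX_ITER = 20


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: segment length and start-to-start step."""

    window: int = 10
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def kabsch(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``Y`` onto ``X``.

    Returns the proper rigid transform ``T`` minimising the (weighted) RMSD
    of ``T(Y)`` to ``X``, together with that minimal RMSD. Reflections are
    excluded by sign-correcting the smallest singular value, the standard
    Kabsch treatment.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"X and Y must both be (N, 3); got {X.shape} and {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be N non-negative values, not all zero")
        w = w / w.sum()

    xc = X - w @ X
    yc = Y - w @ Y
    h = (yc * w[:, None]).T @ xc
    if np.linalg.norm(h) < 1e-15:  # degenerate: no rotational information
        rot = np.eye(3)
        trans = (w @ X) - (w @ Y)
        transform = RigidTransform(rotation=rot, translation=trans)
        delta = X - transform.apply(Y)
        return transform, float(np.sqrt(np.sum(w[:, None] * delta**2)))
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = (w @ X) - rot @ (w @ Y)
    transform = RigidTransform(rotation=rot, translation=trans)
    delta = X - transform.apply(Y)
    rmsd = float(np.sqrt(np.sum(w[:, None] * delta**2)))
    return transform, rmsd


def pairwise_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimal whole-chain CA RMSD between two conformations after superposition."""
    _, rmsd = kabsch(np.asarray(X), np.asarray(Y))
    return rmsd


def _superpose_on_mean(coords: np.ndarray) -> np.ndarray:
    """Superpose every model on an iteratively refined mean structure.

    ``coords`` is (M, N, 3); returns the aligned copy. The reference starts
    from the first model; iteration stops when the mean moves less than
    1e-6 angstrom (RMS) or after 20 rounds.
    """
    aligned = np.array(coords, dtype=float)
    mean = aligned[0].copy()
    for _ in range(_MEAN_MAX_ITER):
        for m in range(aligned.shape[0]):
            transform, _ = kabsch(mean, aligned[m])
            aligned[m] = transform.apply(aligned[m])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < _MEAN_TOL:
            break
    return aligned


def _fluctuation(coords: np.ndarray) -> np.ndarray:
    """Per-residue RMS deviation from the mean after mean-reference superposition."""
    aligned = _superpose_on_mean(coords)
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


def _window_starts(length: int, spec: WindowSpec) -> list[int]:
    starts = list(range(0, length - spec.window + 1, spec.step))
    last = length - spec.window
    if starts[-1] != last:  # anchor the final window on the C-terminus
        starts.append(last)
    return starts


def window_profile(ens: CoordinateEnsemble, spec: WindowSpec = WindowSpec()) -> FlexibilityProfile:
    """Sliding-window per-residue fluctuation profile of an ensemble.

    Every window of ``spec.window`` consecutive residues is superposed
    independently across models (mean-reference, iteratively refined); the
    per-residue fluctuation within each window is the RMS deviation from
    the window mean, and residues covered by several windows get the
    arithmetic mean of their per-window values.
    """
    if ens.n_models < 2:
        raise ValueError("fluctuation is undefined for a single model")
    if ens.n_residues < spec.window:
        raise ValueError(
            f"chain has {ens.n_residues} residues < window {spec.window}; "
            "lower the window size"
        )
    if spec.window < 3:
        raise ValueError("window must span at least 3 residues for superposition")
    total = np.zeros(ens.n_residues)
    count = np.zeros(ens.n_residues)
    for start in _window_starts(ens.n_residues, spec):
        stop = start + spec.window
        fluct = _fluctuation(ens.coords[:, start:stop])
        total[start:stop] += fluct
        count[start:stop] += 1
    return FlexibilityProfile(
        residue_ids=ens.residue_ids, values=total / count, units="angstrom"
    )


def global_profile(ens: CoordinateEnsemble) -> FlexibilityProfile:
    """Per-residue fluctuation after a single whole-chain superposition."""
    if ens.n_models < 2:
        raise ValueError("fluctuation is undefined for a single model")
    if ens.n_residues < 3:
        raise ValueError("need at least 3 residues")
    return FlexibilityProfile(
        residue_ids=ens.residue_ids,
        values=_fluctuation(ens.coords),
        units="angstrom",
    )
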