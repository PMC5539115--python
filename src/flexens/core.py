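"""Core domain containers shared across the pipeline.

The pipeline operates on CA-only traces: a :class:`CoordinateEnsemble` holds
M conformations of the same L residues, a :class:`FlexibilityProfile` holds
one scalar per residue (an RMSD-derived fluctuation in angstroms, or a
unitless predictor score), and a :class:`SecondaryStructureProfile` holds
per-residue three-state secondary structure with probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoordinateEnsemble",
    "FlexibilityProfile",
    "SecondaryStructureProfile",
    "DistanceMatrix",
    "ClusterAssignment",
    "EvaluationRecord",
    "RigidTransform",
    "TMScoreResult",
]

SS_STATES = ("H", "E", "C")


@dataclass(frozen=True)
class CoordinateEnsemble:
    """M aligned conformations of an L-residue CA trace.

    Attributes
    ----------
    residue_ids
        Ordered author residue numbers shared by every model.
    chain_id
        Single-character chain label.
    coords
        Array of shape ``(M, L, 3)``, CA coordinates in angstroms.
    model_labels
        Ordered model identifiers from the source file.
    """

    residue_ids: tuple[int, ...]
    chain_id: str
    coords: np.ndarray
    model_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (M, L, 3), got {coords.shape}")
        m, l, _ = coords.shape
        if m < 1 or l < 1:
            raise ValueError("ensemble needs at least one model and one residue")
        if len(self.residue_ids) != l:
            raise ValueError("residue_ids length does not match coords")
        if len(self.model_labels) != m:
            raise ValueError("model_labels length does not match coords")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def subset_models(self, indices) -> "CoordinateEnsemble":
        """Sub-ensemble containing the models at ``indices`` (order kept)."""
        idx = list(indices)
        return CoordinateEnsemble(
            residue_ids=self.residue_ids,
            chain_id=self.chain_id,
            coords=self.coords[idx],
            model_labels=tuple(self.model_labels[i] for i in idx),
        )


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-residue scalar flexibility values.

    ``units`` is ``"angstrom"`` for RMSD-derived profiles (values must be
    non-negative) and ``"score"`` for unitless predictor output.
    """

    residue_ids: tuple[int, ...]
    values: np.ndarray
    units: str = "score"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "residue_ids", tuple(int(r) for r in self.residue_ids))
        if values.ndim != 1 or len(values) != len(self.residue_ids):
            raise ValueError("values and residue_ids must be 1-D and equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite profile values")
        if self.units not in ("angstrom", "score"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "angstrom" and np.any(values < 0):
            raise ValueError("RMSD-derived values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SecondaryStructureProfile:
    """Per-residue three-state secondary structure (H/E/C) with probabilities.

    ``probs`` is ``(L, 3)`` in (pH, pE, pC) order; each row sums to 1
    within 1e-3.
    """

    residue_ids: tuple[int, ...]
    states: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        n = len(self.residue_ids)
        if len(self.states) != n or probs.shape != (n, 3):
            raise ValueError("states/probs shape mismatch with residue_ids")
        if any(s not in SS_STATES for s in self.states):
            bad = sorted({s for s in self.states if s not in SS_STATES})
            raise ValueError(f"unknown secondary-structure state(s): {bad}")
        if n and np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-3):
            raise ValueError("probability triples must sum to 1 within 1e-3")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise superposed-RMSD matrix over ensemble members (angstrom)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        m = len(self.labels)
        if d.shape != (m, m):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of ensemble members with its silhouette quality."""

    labels: tuple[str, ...]
    cluster_ids: tuple[int, ...]
    k: int
    quality: float

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cluster_ids):
            raise ValueError("labels/cluster_ids length mismatch")
        present = set(self.cluster_ids)
        if present != set(range(self.k)):
            raise ValueError("cluster ids must be exactly 0..k-1 with no empty cluster")

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, c in enumerate(self.cluster_ids) if c == cluster_id]


@dataclass(frozen=True)
class EvaluationRecord:
    """Spearman rank correlation of one predicted profile against a reference."""

    target_id: str
    rs: float
    n_residues: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rs <= 1.0:
            raise ValueError(f"rs out of [-1, 1]: {self.rs}")


@dataclass(frozen=True)
class TMScoreResult:
    """TM-score in (0, 1], with the lengths entering the computation."""

    score: float
    aligned_length: int
    normalization_length: int

    def __post_init__(self) -> None:
        if not 0.0 < self.score <= 1.0 + 1e-12:
            raise ValueError(f"TM-score out of (0, 1]: {self.score}")
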