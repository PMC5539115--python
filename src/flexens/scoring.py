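"""Profile comparison by Spearman rank correlation and evaluation summaries.

Rank correlation is the right metric here because flexibility predictors
report on incompatible scales (angstroms, 1-S2 scores, arbitrary levels):
only the ordering of residues by flexibility is comparable across methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .core import EvaluationRecord, FlexibilityProfile

__all__ = ["spearman_rs", "summarize", "ProfileComparisonError", "EvaluationSummary"]

logger = logging.getLogger(__name__)


class ProfileComparisonError(ValueError):
    """Raised when a rank correlation is undefined (e.g. a constant profile)."""


def _aligned_values(a: FlexibilityProfile, b: FlexibilityProfile) -> tuple[np.ndarray, np.ndarray]:
    if a.residue_ids == b.residue_ids:
        return a.values, b.values
    shared = sorted(set(a.residue_ids) & set(b.residue_ids))
    if not shared:
        raise ProfileComparisonError("profiles share no residues")
    dropped = len(set(a.residue_ids) | set(b.residue_ids)) - len(shared)
    logger.warning("profiles compared on %d shared residues (%d dropped)", len(shared), dropped)
    a_map = dict(zip(a.residue_ids, a.values))
    b_map = dict(zip(b.residue_ids, b.values))
    return (
        np.array([a_map[r] for r in shared]),
        np.array([b_map[r] for r in shared]),
    )


def spearman_rs(a: FlexibilityProfile, b: FlexibilityProfile) -> float:
    """Spearman rank correlation between two per-residue profiles.

    Profiles with mismatched coverage are compared on the shared residues
    (inner join, logged). Ties receive average ranks. A constant profile
    makes the correlation undefined and raises
    :class:`ProfileComparisonError`.
    """
    x, y = _aligned_values(a, b)
    if len(x) < 3:
        raise ProfileComparisonError("need at least 3 shared residues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ProfileComparisonError("constant profile: rank correlation undefined")
    rs = spearmanr(x, y).statistic
    if not np.isfinite(rs):
        raise ProfileComparisonError("rank correlation undefined for these profiles")
    return float(rs)


@dataclass(frozen=True)
class EvaluationSummary:
    """Distributional summary of per-target rank correlations."""

    n: int
    mean: float
    median: float
    n_negative: int
    n_good: int  # rs >= 0.6
    n_excellent: int  # rs >= 0.7

    @property
    def frac_negative(self) -> float:
        return self.n_negative / self.n

    @property
    def frac_good(self) -> float:
        return self.n_good / self.n

    @property
    def frac_excellent(self) -> float:
        return self.n_excellent / self.n


def summarize(records: list[EvaluationRecord]) -> EvaluationSummary:
    """Mean, median and good/excellent tallies over evaluation records.

    "Good" means rs >= 0.6 and "excellent" rs >= 0.7, the conventional
    grades for rank-correlation agreement between flexibility profiles.
    """
    if not records:
        raise ValueError("no evaluation records to summarize")
    rs = np.array([r.rs for r in records])
    return EvaluationSummary(
        n=len(rs),
        mean=float(rs.mean()),
        median=float(np.median(rs)),
        n_negative=int(np.sum(rs < 0)),
        n_good=int(np.sum(rs >= 0.6)),
        n_excellent=int(np.sum(rs >= 0.7)),
    )
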