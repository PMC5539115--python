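"""TM-score structural similarity and the ensemble-vs-ensemble protocol.

TM-score is a length-normalised similarity in (0, 1]:

    TM = (1 / L_ref) * sum_i 1 / (1 + (d_i / d0)^2),
    d0 = 1.24 * (L_ref - 15)^(1/3) - 1.8   (clamped to >= 0.5 A)

where d_i are per-residue distances under the best superposition found.
Because the objective down-weights residues beyond d0, the optimal
superposition generally differs from the least-squares one: it is found by
an iterative fragment-seeded search (seed on the whole chain, halves and
quarters; superpose on the current inlier set; re-select inliers by a
distance cutoff; keep the best score seen).

For ensemble-vs-ensemble quality, each predicted model is scored against
every reference model, the per-model maximum is kept, and those maxima are
averaged over the predicted ensemble. The protocol is deliberately
asymmetric: it asks how well each predicted conformation is represented in
the reference ensemble, normalised by the reference chain length.
"""

from __future__ import annotations

import numpy as np

from .core import CoordinateEnsemble, TMScoreResult
from .superposition import kabsch

__all__ = ["tm_d0", "tm_score", "ensemble_tm", "tm_bin"]

_MAX_REFINE = 20


def tm_d0(n_ref: int) -> float:
    """Length-dependent TM-score normalisation distance, clamped at 0.5 A."""
    if n_ref > 15:
        d0 = 1.24 * (n_ref - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_from_distances(d: np.ndarray, d0: float, n_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / n_norm)


def _seed_fragments(n: int) -> list[np.ndarray]:
    """Seed index sets: the whole chain plus sliding fragments of length
    n/2, n/4 and n/8 (minimum 4), stepped by half their length."""
    seeds = [np.arange(n)]
    for parts in (2, 4, 8):
        size = max(n // parts, 4)
        if size < 3 or size >= n:
            continue
        step = max(size // 2, 1)
        starts = list(range(0, n - size + 1, step))
        if starts[-1] != n - size:
            starts.append(n - size)
        for start in starts:
            seeds.append(np.arange(start, start + size))
    return seeds


def tm_score(model: np.ndarray, ref: np.ndarray) -> TMScoreResult:
    """TM-score of ``model`` against ``ref`` (equal-length CA traces).

    Residue correspondence is positional: both arrays list the same residues
    in the same order (the pipeline compares same-protein ensembles, so no
    alignment search is needed). The score is normalised by the reference
    length.
    """
    model = np.asarray(model, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if model.shape != ref.shape or model.ndim != 2 or model.shape[1] != 3:
        raise ValueError(f"equal-length (L, 3) traces required; got {model.shape} vs {ref.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residues")
    d0 = tm_d0(n)

    best = 0.0
    for seed in _seed_fragments(n):
        # several inlier-cutoff schedules: tight cutoffs lock onto the best
        # local core, looser ones keep more residues in the fit
        for base_cutoff in (d0, d0 + 1.0, 2.0 * d0):
            idx = seed
            for _ in range(_MAX_REFINE):
                transform, _ = kabsch(ref[idx], model[idx])
                moved = transform.apply(model)
                d = np.linalg.norm(moved - ref, axis=1)
                best = max(best, _tm_from_distances(d, d0, n))
                cutoff = base_cutoff
                new_idx = np.flatnonzero(d < cutoff)
                while len(new_idx) < 3:  # relax until the inlier set is usable
                    cutoff += 0.5
                    new_idx = np.flatnonzero(d < cutoff)
                if np.array_equal(new_idx, idx):
                    break
                idx = new_idx
    return TMScoreResult(score=best, aligned_length=n, normalization_length=n)


def ensemble_tm(pred: CoordinateEnsemble, ref: CoordinateEnsemble) -> float:
    """Mean over predicted models of the best TM-score against any reference model."""
    shared = [r for r in pred.residue_ids if r in set(ref.residue_ids)]
    if len(shared) < 3:
        raise ValueError("ensembles share fewer than 3 residues")
    p_idx = [pred.residue_ids.index(r) for r in shared]
    r_idx = [ref.residue_ids.index(r) for r in shared]
    p_coords = pred.coords[:, p_idx]
    r_coords = ref.coords[:, r_idx]
    per_model = [
        max(tm_score(pm, rm).score for rm in r_coords) for pm in p_coords
    ]
    return float(np.mean(per_model))


def tm_bin(tm: float) -> int:
    """Quality bin of a TM-score: 1 [0,0.2), 2 [0.2,0.4), 3 [0.4,0.6), 4 [0.6,1].

    Bin 1 corresponds to random structural agreement, bin 2 to pairs almost
    never sharing a fold class, bin 3 to the fold-assignment phase-transition
    region, bin 4 to confidently same-fold pairs.
    """
    if not 0.0 <= tm <= 1.0:
        raise ValueError(f"TM-score out of [0, 1]: {tm}")
    for b, upper in enumerate((0.2, 0.4, 0.6), start=1):
        if tm < upper:
            return b
    return 4
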