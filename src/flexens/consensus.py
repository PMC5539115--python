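"""Consensus flexibility predictor: a small feed-forward network fusing two
per-residue predictors.

Two flexibility predictors with complementary strengths — one derived from
structural ensembles, one sequence-based (a DynaMine-like 1-S2 score) — are
fused into a single per-residue prediction by a classical one-hidden-layer
feed-forward network with sigmoid activations and bias units in the input
and hidden layers.

Features
--------
Per residue, a sliding window of 9 positions contributes 27 features each:
the two predictor values (min-max normalised over the training set), a
21-slot amino-acid one-hot (20 standard + unknown), the three predicted
secondary-structure probabilities, and a missing-residue flag set for
window positions falling outside the chain (all other slots are zeroed
there). Three global features follow: log chain length and the distances
from the two termini divided by the length. Total: 9 * 27 + 3 = 246.

Targets
-------
Per-residue RMSD values (angstroms, unbounded above) are squashed into
(0, 1) through a logistic transform before training, and network outputs
are mapped back to angstroms through its exact algebraic inverse. The
midpoint and slope of the transform are fitted per training split as the
median and half-interquartile-range of the training RMSD values and stored
with the model.

Cross-validation
----------------
Splits are leave-one-group-out, where groups encode fold-level structural
classes so that no held-out protein has a structural relative in training.
Groups with a single member are pooled into one shared group first.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core import FlexibilityProfile, SecondaryStructureProfile

__all__ = [
    "AMINO_ACIDS",
    "N_FEATURES",
    "FeatureNormalizer",
    "encode_features",
    "logistic_target",
    "inverse_logistic",
    "CVFoldPlan",
    "make_cv_folds",
    "ConsensusModel",
    "TrainingTarget",
    "TrainResult",
    "train",
    "predict",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # one-hot order; index 20 = unknown
WINDOW_DEFAULT = 9
PER_POSITION = 27  # ff + dyn + 21 aa + 3 ss + missing flag
N_GLOBAL = 3
N_FEATURES = WINDOW_DEFAULT * PER_POSITION + N_GLOBAL  # 246


# ---------------------------------------------------------------------------
# logistic squashing of RMSD targets

def logistic_target(rmsd, m: float, s: float):
    """Map an RMSD in angstroms into (0, 1): ``1 / (1 + exp(-(rmsd - m)/s))``."""
    if s <= 0:
        raise ValueError("logistic slope s must be positive")
    return 1.0 / (1.0 + np.exp(-(np.asarray(rmsd, dtype=float) - m) / s))


def inverse_logistic(y, m: float, s: float):
    """Exact inverse of :func:`logistic_target`: ``m + s * ln(y / (1 - y))``.

    Values are clamped to [1e-6, 1 - 1e-6] before inversion so saturated
    network outputs stay finite.
    """
    if s <= 0:
        raise ValueError("logistic slope s must be positive")
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        y = np.clip(y, 1e-6, 1.0 - 1e-6)
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ValueError("inverse logistic needs values in (0, 1)")
    y = np.clip(y, 1e-6, 1.0 - 1e-6)
    return m + s * np.log(y / (1.0 - y))


# ---------------------------------------------------------------------------
# feature encoding

@dataclass(frozen=True)
class FeatureNormalizer:
    """Min-max ranges of the two predictor inputs, fitted on a training set."""

    ff_min: float
    ff_max: float
    dyn_min: float
    dyn_max: float

    @classmethod
    def fit(cls, ff_values: np.ndarray, dyn_values: np.ndarray) -> "FeatureNormalizer":
        return cls(
            ff_min=float(np.min(ff_values)),
            ff_max=float(np.max(ff_values)),
            dyn_min=float(np.min(dyn_values)),
            dyn_max=float(np.max(dyn_values)),
        )

    @staticmethod
    def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi - lo <= 0:
            return np.zeros_like(x)
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def scale_ff(self, x: np.ndarray) -> np.ndarray:
        return self._scale(np.asarray(x, dtype=float), self.ff_min, self.ff_max)

    def scale_dyn(self, x: np.ndarray) -> np.ndarray:
        return self._scale(np.asarray(x, dtype=float), self.dyn_min, self.dyn_max)


def _aa_onehot(aa: str) -> np.ndarray:
    vec = np.zeros(21)
    idx = AMINO_ACIDS.find(aa.upper())
    vec[idx if idx >= 0 else 20] = 1.0
    return vec


def encode_features(
    ff_profile: FlexibilityProfile,
    dyn_profile: FlexibilityProfile,
    seq: str,
    ss: SecondaryStructureProfile,
    window: int = WINDOW_DEFAULT,
    normalizer: FeatureNormalizer | None = None,
) -> np.ndarray:
    """Per-residue feature matrix of shape (L, window * 27 + 3).

    All inputs must cover the same residues in the same order. When no
    ``normalizer`` is given the predictor values are min-max scaled over
    this chain alone (training fits one normaliser over the whole training
    set instead).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    ids = ff_profile.residue_ids
    if dyn_profile.residue_ids != ids or ss.residue_ids != ids or len(seq) != len(ids):
        raise ValueError("ff/dyn/sequence/secondary-structure inputs cover different residues")
    length = len(ids)
    if normalizer is None:
        normalizer = FeatureNormalizer.fit(ff_profile.values, dyn_profile.values)
    ff = normalizer.scale_ff(ff_profile.values)
    dyn = normalizer.scale_dyn(dyn_profile.values)

    half = window // 2
    n_feat = window * PER_POSITION + N_GLOBAL
    out = np.zeros((length, n_feat))
    for i in range(length):
        for w, offset in enumerate(range(-half, half + 1)):
            p = i + offset
            base = w * PER_POSITION
            if 0 <= p < length:
                out[i, base + 0] = ff[p]
                out[i, base + 1] = dyn[p]
                out[i, base + 2 : base + 23] = _aa_onehot(seq[p])
                out[i, base + 23 : base + 26] = ss.probs[p]
            else:
                out[i, base + 26] = 1.0  # missing-residue flag; rest stay zero
        out[i, -3] = np.log(length)
        out[i, -2] = i / length
        out[i, -1] = (length - 1 - i) / length
    return out


# ---------------------------------------------------------------------------
# cross-validation plan

POOLED_GROUP = "__singletons__"


@dataclass(frozen=True)
class CVFoldPlan:
    """Leave-one-group-out plan with singleton groups pooled together."""

    group_of: dict[str, str]
    heldout_groups: tuple[str, ...]

    @property
    def n_splits(self) -> int:
        return len(self.heldout_groups)

    def split_targets(self, group: str) -> tuple[list[str], list[str]]:
        """(training target ids, held-out target ids) for one split."""
        held = [t for t, g in self.group_of.items() if g == group]
        rest = [t for t, g in self.group_of.items() if g != group]
        return rest, held


def make_cv_folds(group_labels: dict[str, str]) -> CVFoldPlan:
    """Build the leave-one-group-out plan from per-target group labels.

    Groups with exactly one member are merged into a single pooled group
    before splitting. At least two groups must remain.
    """
    if not group_labels:
        raise ValueError("no targets")
    counts: dict[str, int] = {}
    for g in group_labels.values():
        counts[g] = counts.get(g, 0) + 1
    pooled = {
        t: (POOLED_GROUP if counts[g] == 1 else g) for t, g in group_labels.items()
    }
    groups = sorted(set(pooled.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups after singleton pooling")
    return CVFoldPlan(group_of=pooled, heldout_groups=tuple(groups))


# ---------------------------------------------------------------------------
# the network

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class ConsensusModel:
    """Trained network weights plus the encoding/transform configuration.

    ``w1`` has shape (n_features + 1, hidden) and ``w2`` (hidden + 1, 1);
    row 0 of each is the bias.
    """

    w1: np.ndarray
    w2: np.ndarray
    hidden_units: int
    logistic_m: float
    logistic_s: float
    normalizer: FeatureNormalizer
    window: int = WINDOW_DEFAULT
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        n_feat = self.window * PER_POSITION + N_GLOBAL
        if self.w1.shape != (n_feat + 1, self.hidden_units):
            raise ValueError(f"w1 shape {self.w1.shape} inconsistent with architecture")
        if self.w2.shape != (self.hidden_units + 1, 1):
            raise ValueError(f"w2 shape {self.w2.shape} inconsistent with architecture")
        if self.logistic_s <= 0:
            raise ValueError("logistic slope must be positive")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "w1": self.w1.tolist(),
            "w2": self.w2.tolist(),
            "hidden_units": self.hidden_units,
            "logistic_m": self.logistic_m,
            "logistic_s": self.logistic_s,
            "window": self.window,
            "seed": self.seed,
            "normalizer": {
                "ff_min": self.normalizer.ff_min,
                "ff_max": self.normalizer.ff_max,
                "dyn_min": self.normalizer.dyn_min,
                "dyn_max": self.normalizer.dyn_max,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ConsensusModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            w1=np.array(payload["w1"]),
            w2=np.array(payload["w2"]),
            hidden_units=payload["hidden_units"],
            logistic_m=payload["logistic_m"],
            logistic_s=payload["logistic_s"],
            window=payload.get("window", WINDOW_DEFAULT),
            seed=payload.get("seed"),
            normalizer=FeatureNormalizer(**payload["normalizer"]),
        )


def _forward(w1: np.ndarray, w2: np.ndarray, x: np.ndarray):
    ones = np.ones((x.shape[0], 1))
    h = _sigmoid(np.hstack([ones, x]) @ w1)
    y = _sigmoid(np.hstack([ones, h]) @ w2)
    return h, y[:, 0]


def predict(model: ConsensusModel, features: np.ndarray) -> np.ndarray:
    """Forward pass; returns per-residue values in (0, 1)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat = model.window * PER_POSITION + N_GLOBAL
    if x.shape[1] != n_feat:
        raise ValueError(f"expected {n_feat} features, got {x.shape[1]}")
    _, y = _forward(model.w1, model.w2, x)
    return y


def predict_profile(
    model: ConsensusModel,
    ff_profile: FlexibilityProfile,
    dyn_profile: FlexibilityProfile,
    seq: str,
    ss: SecondaryStructureProfile,
) -> tuple[FlexibilityProfile, FlexibilityProfile]:
    """Consensus prediction for one chain: (score profile, angstrom profile)."""
    x = encode_features(
        ff_profile, dyn_profile, seq, ss, window=model.window, normalizer=model.normalizer
    )
    y = predict(model, x)
    score = FlexibilityProfile(ff_profile.residue_ids, y, units="score")
    rmsd = inverse_logistic(y, model.logistic_m, model.logistic_s)
    angstrom = FlexibilityProfile(
        ff_profile.residue_ids, np.maximum(rmsd, 0.0), units="angstrom"
    )
    return score, angstrom


# ---------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainingTarget:
    """One protein of a consensus training set."""

    target_id: str
    group: str
    seq: str
    ss: SecondaryStructureProfile
    ff_profile: FlexibilityProfile
    dyn_profile: FlexibilityProfile
    rmsd_profile: FlexibilityProfile  # regression target, angstroms


@dataclass
class TrainResult:
    """Per-split models and the pooled out-of-fold predictions."""

    models: dict[str, ConsensusModel]
    oof_scores: dict[str, FlexibilityProfile]  # (0, 1) network outputs
    oof_angstrom: dict[str, FlexibilityProfile]  # back-transformed profiles
    val_mse: dict[str, float]


def _fit_network(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hidden: int,
    rng: np.random.Generator,
    lr: float,
    max_epochs: int,
    patience: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Full-batch Adam on MSE with early stopping on a validation set."""
    n_in = x_train.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in + 1), size=(n_in + 1, hidden))
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden + 1), size=(hidden + 1, 1))
    m1 = np.zeros_like(w1)
    v1 = np.zeros_like(w1)
    m2 = np.zeros_like(w2)
    v2 = np.zeros_like(w2)
    b1, b2, eps = 0.9, 0.999, 1e-8

    xb = np.hstack([np.ones((x_train.shape[0], 1)), x_train])
    best_val = np.inf
    best = (w1.copy(), w2.copy())
    stale = 0
    for epoch in range(1, max_epochs + 1):
        h = _sigmoid(xb @ w1)
        hb = np.hstack([np.ones((h.shape[0], 1)), h])
        y = _sigmoid(hb @ w2)[:, 0]
        err = y - y_train
        if not np.all(np.isfinite(err)):
            raise FloatingPointError(
                "non-finite training loss; reduce the learning rate"
            )
        # backprop for mean squared error
        n = len(y_train)
        dy = (2.0 / n) * err * y * (1.0 - y)
        g2 = hb.T @ dy[:, None]
        dh = (dy[:, None] @ w2[1:, :].T) * h * (1.0 - h)
        g1 = xb.T @ dh

        m1 = b1 * m1 + (1 - b1) * g1
        v1 = b2 * v1 + (1 - b2) * g1**2
        m2 = b1 * m2 + (1 - b1) * g2
        v2 = b2 * v2 + (1 - b2) * g2**2
        c1 = 1 - b1**epoch
        c2 = 1 - b2**epoch
        w1 -= lr * (m1 / c1) / (np.sqrt(v1 / c2) + eps)
        w2 -= lr * (m2 / c1) / (np.sqrt(v2 / c2) + eps)

        _, y_v = _forward(w1, w2, x_val)
        val = float(np.mean((y_v - y_val) ** 2))
        if val < best_val - tol:
            best_val = val
            best = (w1.copy(), w2.copy())
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return best[0], best[1], best_val


def train(
    dataset: list[TrainingTarget],
    plan: CVFoldPlan,
    hidden: int = 10,
    val_fraction: float = 0.2,
    seed: int = 0,
    lr: float = 0.01,
    max_epochs: int = 2000,
    patience: int = 20,
    tol: float = 1e-5,
) -> TrainResult:
    """Leave-one-group-out training of the consensus network.

    For each split, one group is held out entirely; of the remaining
    targets, a fraction (20% by default, whole targets, never single
    residues) is set aside for early-stopping validation. Training is
    full-batch Adam on the mean squared error of the logistic-squashed
    RMSD targets, stopped when the validation error has not improved by
    ``tol`` for ``patience`` epochs or at ``max_epochs``. Deterministic
    for a given seed.
    """
    by_id = {t.target_id: t for t in dataset}
    if set(by_id) != set(plan.group_of):
        raise ValueError("dataset targets do not match the CV plan")

    models: dict[str, ConsensusModel] = {}
    oof_scores: dict[str, FlexibilityProfile] = {}
    oof_angstrom: dict[str, FlexibilityProfile] = {}
    val_mse: dict[str, float] = {}

    for split_idx, group in enumerate(plan.heldout_groups):
        train_ids, held_ids = plan.split_targets(group)
        rng = np.random.default_rng((seed, split_idx))

        # validation split on whole targets, not residues, to avoid leakage
        order = sorted(train_ids)
        rng.shuffle(order)
        n_val = max(1, int(round(val_fraction * len(order))))
        n_val = min(n_val, len(order) - 1)
        val_ids, fit_ids = order[:n_val], order[n_val:]

        ff_all = np.concatenate([by_id[t].ff_profile.values for t in fit_ids + val_ids])
        dyn_all = np.concatenate([by_id[t].dyn_profile.values for t in fit_ids + val_ids])
        norm = FeatureNormalizer.fit(ff_all, dyn_all)

        rmsd_all = np.concatenate([by_id[t].rmsd_profile.values for t in fit_ids + val_ids])
        m = float(np.median(rmsd_all))
        q75, q25 = np.percentile(rmsd_all, [75, 25])
        s = max(float((q75 - q25) / 2.0), 0.05)

        def encode(tid: str) -> np.ndarray:
            t = by_id[tid]
            return encode_features(
                t.ff_profile, t.dyn_profile, t.seq, t.ss, normalizer=norm
            )

        x_fit = np.vstack([encode(t) for t in fit_ids])
        y_fit = np.concatenate(
            [logistic_target(by_id[t].rmsd_profile.values, m, s) for t in fit_ids]
        )
        x_val = np.vstack([encode(t) for t in val_ids])
        y_val = np.concatenate(
            [logistic_target(by_id[t].rmsd_profile.values, m, s) for t in val_ids]
        )

        w1, w2, best_val = _fit_network(
            x_fit, y_fit, x_val, y_val, hidden, rng, lr, max_epochs, patience, tol
        )
        model = ConsensusModel(
            w1=w1,
            w2=w2,
            hidden_units=hidden,
            logistic_m=m,
            logistic_s=s,
            normalizer=norm,
            seed=seed,
        )
        models[group] = model
        val_mse[group] = best_val

        for tid in held_ids:
            t = by_id[tid]
            score, angstrom = predict_profile(
                model, t.ff_profile, t.dyn_profile, t.seq, t.ss
            )
            oof_scores[tid] = score
            oof_angstrom[tid] = angstrom

    return TrainResult(
        models=models, oof_scores=oof_scores, oof_angstrom=oof_angstrom, val_mse=val_mse
    )
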