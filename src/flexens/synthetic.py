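"""Synthetic fixtures with known ground truth.

Every downstream module is exercised on generated data: CA-trace ensembles
whose per-residue displacement amplitude follows a chosen profile
(optionally contaminated with per-model rigid-body motions), secondary
structure consistent with the base geometry, noisy monotone transforms of
the true flexibility standing in for external predictors, and full
consensus-ready training sets.

The displacement model is deliberately simple: model m is the base trace
plus isotropic Gaussian noise with per-residue, per-coordinate standard
deviation sigma(i). Under this model the true RMSF about the mean is
sigma(i) * sqrt(3), so the generated sigma profile is an exact ground
truth for rank-based recovery checks. Real NMR or predicted ensembles have
correlated, anisotropic displacements; the generator makes no attempt at
physical realism (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .core import CoordinateEnsemble, FlexibilityProfile, SecondaryStructureProfile
from .consensus import TrainingTarget

__all__ = [
    "SyntheticSpec",
    "helix_trace",
    "random_walk_trace",
    "make_ensemble",
    "make_predictor_profile",
    "make_ss_profile",
    "make_sequence",
    "make_training_set",
    "smooth_profile",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ensemble."""

    length: int
    n_models: int
    sigma_profile: np.ndarray
    rigid_contamination: bool = False
    seed: int = 0
    base_geometry: str = "helix"  # or "random_walk"

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma_profile, dtype=float)
        object.__setattr__(self, "sigma_profile", sigma)
        if self.length < 1 or self.n_models < 2:
            raise ValueError("need length >= 1 and at least 2 models")
        if sigma.shape != (self.length,) or np.any(sigma < 0):
            raise ValueError("sigma_profile must be length-L and non-negative")
        if self.base_geometry not in ("helix", "random_walk"):
            raise ValueError(f"unknown base geometry {self.base_geometry!r}")


def helix_trace(length: int) -> np.ndarray:
    """Ideal alpha-helical CA trace: 1.5 A rise, 100 deg turn, 2.3 A radius."""
    i = np.arange(length)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def random_walk_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with 3.8 A CA-CA steps.

    Steps that would come within 3.0 A of an earlier position are resampled
    (up to 200 attempts, after which the clash is accepted — adequate for
    the short chains used in tests).
    """
    coords = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) >= 3.0:
                break
        coords[i] = cand
    return coords


def make_ensemble(spec: SyntheticSpec) -> tuple[CoordinateEnsemble, FlexibilityProfile]:
    """Generate an ensemble and return it with its ground-truth sigma profile."""
    rng = np.random.default_rng(spec.seed)
    if spec.base_geometry == "helix":
        base = helix_trace(spec.length)
    else:
        base = random_walk_trace(spec.length, rng)

    sigma = spec.sigma_profile
    coords = np.empty((spec.n_models, spec.length, 3))
    for m in range(spec.n_models):
        model = base + rng.normal(size=(spec.length, 3)) * sigma[:, None]
        if spec.rigid_contamination:
            rot = Rotation.random(random_state=rng).as_matrix()
            trans = rng.uniform(-20.0, 20.0, size=3)
            model = model @ rot.T + trans
        coords[m] = model

    ens = CoordinateEnsemble(
        residue_ids=tuple(range(1, spec.length + 1)),
        chain_id="A",
        coords=coords,
        model_labels=tuple(str(m + 1) for m in range(spec.n_models)),
    )
    truth = FlexibilityProfile(ens.residue_ids, sigma.copy(), units="angstrom")
    return ens, truth


def make_predictor_profile(
    truth: FlexibilityProfile,
    transform: str = "affine",
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
    offset: float = 0.0,
) -> FlexibilityProfile:
    """Noisy monotone transform of a true profile (an external-predictor stand-in).

    ``transform`` is ``"affine"`` (``scale * x + offset``, scale > 0) or
    ``"logistic"`` (squashed around the profile median). With zero noise the
    result is rank-identical to the truth.
    """
    rng = np.random.default_rng(seed)
    x = truth.values
    if transform == "affine":
        if scale <= 0:
            raise ValueError("affine scale must be positive to stay monotone")
        g = scale * x + offset
    elif transform == "logistic":
        s = max(np.std(x) / 2.0, 1e-6)
        g = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / s))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    values = g + rng.normal(scale=noise_sd, size=len(x))
    return FlexibilityProfile(truth.residue_ids, values, units="score")


def make_ss_profile(
    states: str, residue_ids=None, confidence: float = 0.9
) -> SecondaryStructureProfile:
    """Secondary-structure profile from a state string, with peaked probabilities."""
    if residue_ids is None:
        residue_ids = tuple(range(1, len(states) + 1))
    rest = (1.0 - confidence) / 2.0
    probs = np.empty((len(states), 3))
    for i, s in enumerate(states):
        row = {"H": 0, "E": 1, "C": 2}[s]
        probs[i] = rest
        probs[i, row] = confidence
    return SecondaryStructureProfile(
        residue_ids=tuple(residue_ids), states=tuple(states), probs=probs
    )


def make_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def smooth_profile(
    length: int, rng: np.random.Generator, lo: float, hi: float, smoothness: float = 4.0
) -> np.ndarray:
    """Smooth random profile scaled into [lo, hi] (Gaussian-filtered noise)."""
    raw = gaussian_filter1d(rng.normal(size=length), smoothness, mode="nearest")
    span = np.ptp(raw)
    if span == 0:
        return np.full(length, (lo + hi) / 2.0)
    return lo + (hi - lo) * (raw - raw.min()) / span


def _ss_from_sigma(sigma: np.ndarray) -> str:
    """Low-flexibility residues read as helix, high as coil, middle as strand."""
    lo, hi = np.percentile(sigma, [33, 66])
    return "".join("H" if s <= lo else ("E" if s <= hi else "C") for s in sigma)


def make_training_set(
    n_targets: int,
    n_groups: int,
    length: int = 50,
    n_models: int = 20,
    mode: str = "complementary",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[TrainingTarget], dict[str, str]]:
    """Consensus-ready dataset with known ground truth.

    Returns the targets and their group labels (round-robin over
    ``n_groups`` fold classes). Three signal structures are available:

    - ``"complementary"``: the true flexibility is the sum of two smooth
      components and each predictor reports (a noisy monotone transform of)
      one component only — fusing both is required to recover the truth.
    - ``"redundant"``: both predictors are noisy monotone transforms of the
      full truth.
    - ``"planted_linear"``: the regression target is exactly a noiseless
      linear combination of the two predictor profiles (no ensemble is
      generated) — a recoverability control for the trainer.

    In the ensemble-backed modes the regression target is the
    sliding-window fluctuation profile of a generated ensemble whose
    displacement amplitude is the true profile.
    """
    from .superposition import window_profile  # local import to avoid a cycle

    if mode not in ("complementary", "redundant", "planted_linear"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    targets: list[TrainingTarget] = []
    groups: dict[str, str] = {}
    for n in range(n_targets):
        tid = f"T{n:03d}"
        group = f"G{n % n_groups}"
        groups[tid] = group
        seq = make_sequence(length, rng)
        rids = tuple(range(1, length + 1))

        if mode == "planted_linear":
            p1 = smooth_profile(length, rng, 0.0, 1.0)
            p2 = smooth_profile(length, rng, 0.0, 1.0)
            rmsd = 0.3 + 2.0 * (0.5 * p1 + 0.5 * p2)
            sigma = rmsd
            ff = FlexibilityProfile(rids, p1, units="score")
            dyn = FlexibilityProfile(rids, p2, units="score")
            target = FlexibilityProfile(rids, rmsd, units="angstrom")
        else:
            comp_a = smooth_profile(length, rng, 0.05, 1.2, smoothness=5.0)
            comp_b = smooth_profile(length, rng, 0.05, 1.2, smoothness=5.0)
            sigma = 0.1 + comp_a + comp_b
            spec = SyntheticSpec(
                length=length,
                n_models=n_models,
                sigma_profile=sigma,
                seed=int(rng.integers(2**31)),
            )
            ens, _ = make_ensemble(spec)
            target = window_profile(ens)
            if mode == "complementary":
                src1, src2 = comp_a, comp_b
            else:
                src1 = src2 = sigma
            ff = make_predictor_profile(
                FlexibilityProfile(rids, src1, units="score"),
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            dyn = make_predictor_profile(
                FlexibilityProfile(rids, src2, units="score"),
                transform="logistic",
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
        ss = make_ss_profile(_ss_from_sigma(np.asarray(sigma)), rids)
        targets.append(
            TrainingTarget(
                target_id=tid,
                group=group,
                seq=seq,
                ss=ss,
                ff_profile=ff,
                dyn_profile=dyn,
                rmsd_profile=target,
            )
        )
    return targets, groups
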