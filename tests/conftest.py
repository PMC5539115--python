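import numpy as np
import pytest

from flexens import CoordinateEnsemble, SyntheticSpec, make_ensemble
from flexens.synthetic import helix_trace


@pytest.fixture
def helix_ensemble():
    """50-model, 60-residue ensemble with a smooth 6x flexibility contrast."""
    sigma = np.linspace(0.3, 1.8, 60)
    ens, truth = make_ensemble(
        SyntheticSpec(length=60, n_models=50, sigma_profile=sigma, seed=11)
    )
    return ens, truth


@pytest.fixture
def rigid_ensemble():
    """Identical conformations scattered by per-model rigid-body motions."""
    ens, _ = make_ensemble(
        SyntheticSpec(
            length=40,
            n_models=12,
            sigma_profile=np.zeros(40),
            rigid_contamination=True,
            seed=4,
        )
    )
    return ens


def planted_ensemble(sizes, spread=10.0, intra=0.1, length=30, seed=0):
    """Ensemble of well-separated conformational groups with tight members."""
    rng = np.random.default_rng(seed)
    base = helix_trace(length)
    coords = []
    for size in sizes:
        center = base + rng.normal(size=(length, 3)) * spread
        for _ in range(size):
            coords.append(center + rng.normal(size=(length, 3)) * intra / np.sqrt(3))
    return CoordinateEnsemble(
        residue_ids=tuple(range(1, length + 1)),
        chain_id="A",
        coords=np.array(coords),
        model_labels=tuple(str(i) for i in range(sum(sizes))),
    )


@pytest.fixture
def planted_864():
    return planted_ensemble([8, 6, 4], seed=1)
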