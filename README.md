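# flexens

Backbone-flexibility profiles from protein structural ensembles.

Intrinsically disordered proteins and flexible regions of folded proteins
are poorly served by a binary order/disorder label: what an NMR ensemble
actually reports is *how much* each residue moves. `flexens` turns a
multi-model structural ensemble — an NMR-style PDB entry or a set of
predicted models — into a per-residue flexibility profile, and provides the
surrounding machinery needed to evaluate and improve such predictions:

- **Sliding-window superposition profiles.** Short overlapping segments
  (10 residues by default) are superposed independently across models, so
  per-model rigid-body motions cancel and only internal flexibility
  remains. Each residue's value is its RMS fluctuation about the local mean
  structure, averaged over the windows covering it (an RMSF in angstroms).
  A whole-chain ("global") superposition profile is included for contrast:
  it lets mobile tails inflate the apparent flexibility of rigid cores.
- **Final-ensemble extraction.** A raw model set is reduced to a final
  ensemble by average-linkage clustering of the pairwise superposed-RMSD
  matrix, with the number of clusters chosen to maximise the mean
  silhouette width; the largest cluster is kept.
- **Profile scoring.** Profiles from different methods live on
  incompatible scales, so agreement is measured by Spearman's rank
  correlation R_S; summaries count "good" (R_S ≥ 0.6) and "excellent"
  (R_S ≥ 0.7) predictions.
- **Structure-prediction quality.** TM-score
  (TM = L⁻¹ Σᵢ 1/(1+(dᵢ/d₀)²), d₀ = 1.24·(L−15)^⅓ − 1.8, clamped at
  0.5 Å) with an ensemble-vs-ensemble protocol: mean over predicted models
  of the best score against any reference model, plus the standard
  0.2/0.4/0.6 quality bins.
- **A naive baseline** assigning coil > strand > helix flexibility from
  predicted secondary structure.
- **A consensus predictor**: a one-hidden-layer feed-forward network
  (10 hidden units, sigmoid activations, 246 inputs from a 9-residue
  feature window) that fuses an ensemble-derived profile with a
  sequence-based predictor score, trained with leave-one-fold-group-out
  cross-validation on logistic-squashed RMSD targets.
- **A synthetic-data generator** producing ensembles with known
  per-residue displacement amplitudes, secondary structures, noisy
  predictor stand-ins and full training sets, so the whole pipeline is
  testable without any external predictors or the PDB.

## Worked example

```python
import numpy as np
from flexens import (SyntheticSpec, WindowSpec, make_ensemble,
                     window_profile, global_profile, spearman_rs)

sigma = np.linspace(0.3, 1.8, 60)          # true flexibility, 6x ramp
ens, truth = make_ensemble(
    SyntheticSpec(length=60, n_models=50, sigma_profile=sigma, seed=11))

wp = window_profile(ens, WindowSpec(window=10))
print(round(wp.values[0], 2), round(wp.values[-1], 2))   # 0.52 2.75
print(round(spearman_rs(wp, truth), 3))                  # 0.993
```

The profile values are RMS fluctuations in angstroms: the last residue of
the chain moves about six times more than the first, matching the imposed
amplitude ramp, and the rank agreement with the true profile is 0.993.
The scripts in `examples/` walk through each capability (profiles,
ensemble extraction, TM-score quality, the naive baseline, consensus
training) with printed output and an explanation of the numbers.

A thin CLI mirrors the library for shell use:

```sh
flexens synth-ensemble --length 60 --models 50 --profile step:0.2,2.0@40 --seed 1 --out raw.pdb
flexens cluster --pdb raw.pdb --out final.pdb
flexens profile --pdb final.pdb --window 10 --mode window --out prof.tsv
flexens compare --pred prof.tsv --ref other.tsv
```

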