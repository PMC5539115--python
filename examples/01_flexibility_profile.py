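"""Per-residue flexibility from an ensemble: sliding-window vs global superposition.

Builds a 50-model synthetic ensemble of a 60-residue chain whose true
per-residue displacement amplitude ramps from 0.3 to 1.8 A, then compares
the windowed fluctuation profile with the single whole-chain superposition.
"""

import numpy as np

from flexens import (
    SyntheticSpec,
    WindowSpec,
    global_profile,
    make_ensemble,
    spearman_rs,
    window_profile,
)

sigma = np.linspace(0.3, 1.8, 60)
ens, truth = make_ensemble(
    SyntheticSpec(length=60, n_models=50, sigma_profile=sigma, seed=11)
)

wp = window_profile(ens, WindowSpec(window=10))
gp = global_profile(ens)

print(f"ensemble: {ens.n_models} models x {ens.n_residues} residues")
print(f"window profile,  first/last residue: {wp.values[0]:.2f} / {wp.values[-1]:.2f} A")
print(f"global profile,  first/last residue: {gp.values[0]:.2f} / {gp.values[-1]:.2f} A")
print(f"rank agreement with the true amplitude: window R_S = {spearman_rs(wp, truth):.3f}, "
      f"global R_S = {spearman_rs(gp, truth):.3f}")
print()
print("The windowed profile tracks the imposed flexibility ramp almost")
print("perfectly; values are RMS fluctuations about the local mean structure")
print("in angstroms, so the last residue moves ~6x more than the first.")
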