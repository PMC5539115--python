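"""Naive flexibility assignment from predicted secondary structure.

The baseline assumes flexibility is ordered coil > strand > helix: loops
move most, sheets are intermediate, helices are most rigid. Because the
downstream comparison is rank-based, only this ordering matters — any
numeric levels with C > E > H produce identical rank correlations.
"""

from __future__ import annotations

import numpy as np

from .core import FlexibilityProfile, SecondaryStructureProfile

__all__ = ["naive_profile", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = {"C": 3.0, "E": 2.0, "H": 1.0}


def naive_profile(
    ss: SecondaryStructureProfile, levels: dict[str, float] | None = None
) -> FlexibilityProfile:
    """Per-residue flexibility level from the predicted H/E/C state."""
    if levels is None:
        levels = DEFAULT_LEVELS
    if not levels.get("C", 0) > levels.get("E", 0) > levels.get("H", 0):
        raise ValueError("levels must be ordered C > E > H")
    unknown = sorted(set(ss.states) - set(levels))
    if unknown:
        raise ValueError(f"no level for state(s): {unknown}")
    values = np.array([levels[s] for s in ss.states])
    return FlexibilityProfile(residue_ids=ss.residue_ids, values=values, units="score")
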