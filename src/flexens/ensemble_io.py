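"""Reading and writing the file formats the pipeline touches.

Structural input is multi-model PDB (NMR-style ensembles or predicted model
sets), reduced to CA-only traces. Per-residue scalar predictions travel as
two-column text and secondary structure as PSIPRED VFORMAT ``.ss2`` files.
"""

from __future__ import annotations

import logging
import os

import gemmi
import numpy as np

from .core import CoordinateEnsemble, FlexibilityProfile, SecondaryStructureProfile

__all__ = [
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_ss2",
    "write_ss2",
    "read_scalar_profile",
    "write_profile",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


def read_multimodel_pdb(path: str | os.PathLike, chain: str | None = None) -> CoordinateEnsemble:
    """Build a CA-only :class:`CoordinateEnsemble` from a multi-model PDB file.

    Residues lacking a CA atom in *any* model are dropped from all models
    (intersection rule) so the coordinate array stays rectangular; dropped
    residue ids are logged. For residues with alternate locations the first
    altLoc is kept. Insertion codes are rejected.

    Parameters
    ----------
    path
        PDB file with one or more MODEL records (a single implicit model is
        accepted).
    chain
        Chain to extract; may be omitted when the file has exactly one chain.
    """
    structure = gemmi.read_structure(os.fspath(path), format=gemmi.CoorFormat.Pdb)
    if len(structure) == 0:
        raise FormatError(f"{path}: no models found")

    chain_names = sorted({ch.name for model in structure for ch in model})
    if chain is None:
        if len(chain_names) != 1:
            raise FormatError(
                f"{path}: multiple chains {chain_names}; specify one explicitly"
            )
        chain = chain_names[0]
    elif chain not in chain_names:
        raise FormatError(f"{path}: chain {chain!r} not present (has {chain_names})")

    per_model: list[dict[int, np.ndarray]] = []
    orders: list[list[int]] = []
    model_labels: list[str] = []
    for model in structure:
        ca: dict[int, np.ndarray] = {}
        order: list[int] = []
        for ch in model:
            if ch.name != chain:
                continue
            for res in ch:
                if res.seqid.icode not in (" ", "\0", ""):
                    raise FormatError(
                        f"{path}: insertion code {res.seqid.icode!r} at residue "
                        f"{res.seqid.num} is not supported"
                    )
                atom = res.find_atom("CA", "*")
                if atom is None:
                    continue
                rid = res.seqid.num
                if rid not in ca:  # first occurrence wins (first altLoc)
                    ca[rid] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    order.append(rid)
        per_model.append(ca)
        orders.append(order)
        model_labels.append(str(model.num))

    if not any(per_model):
        raise FormatError(f"{path}: no CA atoms found in chain {chain!r}")

    common = set(per_model[0])
    for ca in per_model[1:]:
        common &= set(ca)
    if not common:
        raise FormatError(f"{path}: models share no residues with CA atoms")

    kept = [rid for rid in orders[0] if rid in common]
    dropped = sorted(set().union(*(set(o) for o in orders)) - common)
    if dropped:
        logger.warning(
            "%s: dropped residues missing CA in some model: %s", path, dropped
        )

    coords = np.array([[ca[rid] for rid in kept] for ca in per_model])
    return CoordinateEnsemble(
        residue_ids=tuple(kept),
        chain_id=chain,
        coords=coords,
        model_labels=tuple(model_labels),
    )


def write_multimodel_pdb(ens: CoordinateEnsemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB file (CA-only, ALA placeholders)."""
    structure = gemmi.Structure()
    structure.name = "flexens ensemble"
    for m in range(ens.n_models):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain(ens.chain_id)
        for rid, xyz in zip(ens.residue_ids, ens.coords[m]):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(rid), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(os.fspath(path))


def read_ss2(path: str | os.PathLike) -> SecondaryStructureProfile:
    """Parse a PSIPRED VFORMAT ``.ss2`` file.

    Each body line carries ``index residue state pC pH pE``; the returned
    probabilities are reordered to (pH, pE, pC).
    """
    residue_ids: list[int] = []
    states: list[str] = []
    probs: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            try:
                rid = int(fields[0])
                p_c, p_h, p_e = (float(x) for x in fields[3:6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            state = fields[2]
            if state not in ("H", "E", "C"):
                raise FormatError(f"{path}:{lineno}: unknown state {state!r}")
            residue_ids.append(rid)
            states.append(state)
            probs.append((p_h, p_e, p_c))
    if not residue_ids:
        raise FormatError(f"{path}: no residue lines found")
    return SecondaryStructureProfile(
        residue_ids=tuple(residue_ids),
        states=tuple(states),
        probs=np.array(probs),
    )


def write_ss2(
    ss: SecondaryStructureProfile, path: str | os.PathLike, seq: str | None = None
) -> None:
    """Write a profile in PSIPRED VFORMAT (columns: idx, aa, state, pC, pH, pE)."""
    if seq is not None and len(seq) != len(ss):
        raise ValueError("sequence length does not match profile")
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (flexens synthetic)\n\n")
        for i, (rid, state) in enumerate(zip(ss.residue_ids, ss.states)):
            aa = seq[i] if seq is not None else "A"
            p_h, p_e, p_c = ss.probs[i]
            fh.write(f"{rid:4d} {aa} {state}  {p_c:6.3f} {p_h:6.3f} {p_e:6.3f}\n")


def read_scalar_profile(path: str | os.PathLike) -> FlexibilityProfile:
    """Read a two-column (residue index, value) per-residue profile.

    Lines starting with ``#`` are comments; a ``# units=...`` comment sets the
    profile units (default ``score``). Residue indices must be strictly
    increasing.
    """
    units = "score"
    residue_ids: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("units="):
                    units = body.split("=", 1)[1].strip()
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                rid = int(fields[0])
                val = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if residue_ids and rid <= residue_ids[-1]:
                raise FormatError(
                    f"{path}:{lineno}: residue index {rid} not strictly increasing"
                )
            residue_ids.append(rid)
            values.append(val)
    return FlexibilityProfile(
        residue_ids=tuple(residue_ids), values=np.array(values), units=units
    )


def write_profile(profile: FlexibilityProfile, path: str | os.PathLike) -> None:
    """Write a profile as tab-separated text with a ``# units=`` header.

    Values carry 6 significant digits, enough to round-trip through
    :func:`read_scalar_profile` at the tested precision.
    """
    with open(path, "w") as fh:
        fh.write(f"# units={profile.units}\n")
        for rid, val in zip(profile.residue_ids, profile.values):
            fh.write(f"{rid}\t{val:.6g}\n")
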