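"""Structure and profile file I/O.

Structures are read with gemmi (PDB and mmCIF, multi-model aware).  Waters,
alternate locations other than blank/'A', and zero-occupancy atoms are
dropped at parse time, and each drop is logged.  Profiles use the common
text conventions: P(r) as two whitespace-separated columns (r, P) under
'#' comment headers, I(q) as an ATSAS-style three-column .dat (q, I, sigma).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .errors import FileFormatError, InvalidParameterError
from .profile import PrCurve, ScatteringProfile
from .structures import AtomicStructure, ConformerEnsemble

logger = logging.getLogger("saxsfold")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_structure(path: str | Path) -> AtomicStructure | ConformerEnsemble:
    """Parse a PDB or mmCIF file.

    Single-model files yield an :class:`AtomicStructure`; multi-model files a
    :class:`ConformerEnsemble` with one structure per MODEL block, order
    preserved.  Waters, non-'A' altlocs, and zero-occupancy atoms are
    skipped.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    models = []
    for i, model in enumerate(st):
        structure = _convert_model(model, model_id=i + 1, label=path.name)
        if structure.n_atoms:
            models.append(structure)
    if not models:
        raise FileFormatError(f"{path}: no atoms after filtering")
    if len(models) == 1:
        return models[0]
    return ConformerEnsemble(entry_id=path.stem, models=models)


def _convert_model(model: "gemmi.Model", model_id: int, label: str) -> AtomicStructure:
    elements, z, coords = [], [], []
    chain_ids, res_indices, res_names, atom_names = [], [], [], []
    n_dropped = 0
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES or residue.is_water():
                n_dropped += len(residue)
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    n_dropped += 1
                    continue
                if atom.occ == 0:
                    n_dropped += 1
                    continue
                elements.append(atom.element.name.upper())
                z.append(max(atom.element.atomic_number, 1))
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chain_ids.append(chain.name)
                res_indices.append(residue.seqid.num)
                res_names.append(residue.name)
                atom_names.append(atom.name)
    if n_dropped:
        logger.info("%s model %d: dropped %d atoms (water/altloc/occupancy policy)",
                    label, model_id, n_dropped)
    return AtomicStructure(
        elements=elements, z=np.array(z, dtype=np.int64),
        coords=np.array(coords, dtype=np.float64).reshape(-1, 3),
        chain_ids=chain_ids, res_indices=np.array(res_indices, dtype=np.int64),
        res_names=res_names, atom_names=atom_names, model_id=model_id,
    )


def _pdb_atom_line(serial: int, atom_name: str, res_name: str, chain: str,
                   res_idx: int, xyz: np.ndarray, element: str) -> str:
    name = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s}{res_name:>4s} {chain:1s}{res_idx:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{element.capitalize():>2s}"
    )


def write_pdb(obj: AtomicStructure | ConformerEnsemble, path: str | Path) -> None:
    """Write a structure (or a multi-model ensemble) as a PDB file."""
    path = Path(path)
    models = obj.models if isinstance(obj, ConformerEnsemble) else [obj]
    multi = len(models) > 1
    lines: list[str] = []
    for structure in models:
        if multi:
            lines.append(f"MODEL     {structure.model_id:4d}")
        serial = 0
        for i in range(structure.n_atoms):
            serial += 1
            lines.append(_pdb_atom_line(
                serial, structure.atom_names[i], structure.res_names[i],
                structure.chain_ids[i][:1] or "A", int(structure.res_indices[i]),
                structure.coords[i], structure.elements[i],
            ))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_mmcif(obj: AtomicStructure | ConformerEnsemble, path: str | Path) -> None:
    """Write a structure as mmCIF (via a PDB-shaped gemmi round trip)."""
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".pdb", mode="w", delete=False) as tmp:
        tmp_path = tmp.name
    write_pdb(obj, tmp_path)
    st = gemmi.read_structure(tmp_path)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
    Path(tmp_path).unlink()


def write_pr(pr: PrCurve, path: str | Path) -> None:
    """Two-column P(r) text file with a '#' metadata header."""
    path = Path(path)
    header = [
        f"# dr {pr.dr:.6g}",
        f"# dmax {pr.dmax:.6g}",
        f"# normalized {int(pr.normalized)}",
        f"# self_term {pr.self_term:.10g}",
        f"# total_weight {'' if pr.total_weight is None else format(pr.total_weight, '.10g')}",
    ]
    body = [f"{r:.6f} {p:.10e}" for r, p in zip(pr.r, pr.p)]
    path.write_text("\n".join(header + body) + "\n")


def read_pr(path: str | Path) -> PrCurve:
    """Read a two-column P(r) file written by :func:`write_pr` (or any plain
    two-column r, P text)."""
    path = Path(path)
    meta = {"dr": None, "dmax": None, "normalized": 0, "self_term": 0.0,
            "total_weight": None}
    r_vals, p_vals = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            parts = text[1:].split()
            if len(parts) >= 1 and parts[0] in meta:
                meta[parts[0]] = float(parts[1]) if len(parts) > 1 else None
            continue
        parts = text.split()
        if len(parts) < 2:
            raise FileFormatError(f"{path}:{lineno}: expected two columns, got {text!r}")
        try:
            r_vals.append(float(parts[0]))
            p_vals.append(float(parts[1]))
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(r_vals) < 2:
        raise FileFormatError(f"{path}: fewer than two data rows")
    r = np.array(r_vals)
    dr = meta["dr"] if meta["dr"] else float(r[1] - r[0])
    dmax = meta["dmax"] if meta["dmax"] else float(r[np.array(p_vals) > 0].max(initial=r[-1]))
    return PrCurve(
        r=r, p=np.array(p_vals), dr=dr, dmax=dmax,
        normalized=bool(meta["normalized"]),
        self_term=float(meta["self_term"] or 0.0),
        total_weight=meta["total_weight"],
    )


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """ATSAS-style three-column .dat: q, I, sigma (blank when absent)."""
    path = Path(path)
    lines = ["# q I sigma"]
    for k in range(len(profile)):
        sig = "" if profile.sigma is None else f" {profile.sigma[k]:.10e}"
        lines.append(f"{profile.q[k]:.6f} {profile.i[k]:.10e}{sig}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path, q_units: str = "A^-1") -> ScatteringProfile:
    """Read a 2- or 3-column scattering profile.

    ``q_units`` may be ``"A^-1"`` (default) or ``"nm^-1"`` (converted).
    A profile without a third column has no uncertainties.
    """
    path = Path(path)
    if q_units not in ("A^-1", "nm^-1"):
        raise InvalidParameterError(f"unknown q units {q_units!r}")
    q_vals, i_vals, s_vals = [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        if len(parts) < 2:
            raise FileFormatError(f"{path}:{lineno}: expected >= 2 columns, got {text!r}")
        try:
            q_vals.append(float(parts[0]))
            i_vals.append(float(parts[1]))
            if len(parts) >= 3:
                s_vals.append(float(parts[2]))
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    if not q_vals:
        raise FileFormatError(f"{path}: no data rows")
    if s_vals and len(s_vals) != len(q_vals):
        raise FileFormatError(f"{path}: sigma column present on only some rows")
    q = np.array(q_vals)
    if q_units == "nm^-1":
        q = q / 10.0
    return ScatteringProfile(
        q=q, i=np.array(i_vals),
        sigma=np.array(s_vals) if s_vals else None,
    )
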