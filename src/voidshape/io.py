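"""Reading and writing molecular snapshots, meshes and result tables.

Coordinate files (GRO, PDB, XYZ) are handled through MDAnalysis; the package
works in Angstrom internally (MDAnalysis already converts GRO's nm).  The
solute is identified by a selector — a residue name or an explicit list of
0-based atom indices — and everything else is treated as water whose O/H
spheres get vdW radii 1.52/1.2 A.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .synthetic import (
    SolvatedConfiguration,
    VDW_RADIUS_H,
    VDW_RADIUS_O,
)

# Bondi-style vdW radii for common solute elements, Angstrom
SOLUTE_VDW = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
}


def _element_of(atom) -> str:
    try:
        el = atom.element
        if el:
            return el.upper()
    except Exception:
        pass
    name = atom.name.strip()
    # strip leading digits, take the leading alphabetic run
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in SOLUTE_VDW:
        return stripped[:2].upper()
    return stripped[:1].upper()


def _group_of(atom_name: str, element: str) -> str:
    """Heuristic terminal-group label for facet counting.

    Backbone-amine-like names (N, H1..H3, NT...) map to ``N-term``,
    carboxylate-like names (C, O, OXT, OC1, OC2) to ``C-term``, everything
    else to ``side``.
    """
    n = atom_name.strip().upper()
    if n in ("N", "NT") or (element == "N" and n.startswith("NT")):
        return "N-term"
    if n in ("C", "O", "OXT", "OC1", "OC2", "OT1", "OT2"):
        return "C-term"
    return "side"


def read_configuration(
    path,
    fmt: str | None = None,
    solute_selector=None,
    box: tuple[float, float, float] | None = None,
    frame_id: int = 0,
) -> SolvatedConfiguration:
    """Read a GRO/PDB/XYZ snapshot into a :class:`SolvatedConfiguration`.

    ``solute_selector`` is a residue name (str) or a list of 0-based atom
    indices; None means the file holds pure solvent.  ``box`` (Angstrom)
    overrides or supplies missing box vectors (XYZ files carry none).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)

    if box is not None:
        box_a = np.asarray(box, dtype=float)
    else:
        dims = u.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            raise ValueError(
                f"{path.name}: no box in file; pass box=(lx, ly, lz) in A")
        if np.any(np.abs(np.asarray(dims[3:6]) - 90.0) > 1e-3):
            raise ValueError(f"{path.name}: only orthorhombic boxes supported")
        box_a = np.asarray(dims[:3], dtype=float)

    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise ValueError(f"{path.name}: empty file")

    if solute_selector is None:
        solute_mask = np.zeros(n, dtype=bool)
    elif isinstance(solute_selector, str):
        sel = atoms.select_atoms(f"resname {solute_selector}")
        if len(sel) == 0:
            raise ValueError(
                f"{path.name}: selector resname {solute_selector!r} matches "
                "no atoms")
        solute_mask = np.zeros(n, dtype=bool)
        solute_mask[sel.indices] = True
    else:
        idx = np.asarray(list(solute_selector), dtype=int)
        if len(idx) == 0:
            raise ValueError("empty solute index list")
        solute_mask = np.zeros(n, dtype=bool)
        solute_mask[idx] = True

    positions = atoms.positions.astype(float)
    elements = [_element_of(a) for a in atoms]

    sol_idx = np.flatnonzero(solute_mask)
    wat_idx = np.flatnonzero(~solute_mask)

    solute_radii = []
    for i in sol_idx:
        el = elements[i]
        if el not in SOLUTE_VDW:
            raise ValueError(
                f"{path.name}: unknown element {el!r} for solute atom "
                f"{atoms[i].name} (index {i})")
        solute_radii.append(SOLUTE_VDW[el])

    solvent_radii = []
    for i in wat_idx:
        el = elements[i]
        if el == "O":
            solvent_radii.append(VDW_RADIUS_O)
        elif el == "H":
            solvent_radii.append(VDW_RADIUS_H)
        else:
            raise ValueError(
                f"{path.name}: solvent atom {atoms[i].name} (index {i}) has "
                f"element {el!r}; only O/H water is supported")

    return SolvatedConfiguration(
        box=box_a,
        solute_pos=positions[sol_idx],
        solute_elements=[elements[i] for i in sol_idx],
        solute_radii=np.asarray(solute_radii),
        solute_groups=[_group_of(atoms[i].name, elements[i]) for i in sol_idx],
        solvent_pos=positions[wat_idx],
        solvent_elements=[elements[i] for i in wat_idx],
        solvent_radii=np.asarray(solvent_radii),
        frame_id=frame_id,
    )


def write_configuration(config: SolvatedConfiguration, path,
                        solute_resname: str = "LIG") -> None:
    """Write a configuration as GRO or PDB (by file extension)."""
    import MDAnalysis as mda

    path = Path(path)
    n_sol = config.n_solute
    n_wat = config.n_waters
    n_atoms = n_sol + config.n_solvent
    n_res = (1 if n_sol else 0) + n_wat

    u = mda.Universe.empty(n_atoms, n_residues=n_res,
                           atom_resindex=_resindex(n_sol, n_wat),
                           trajectory=True)
    names = []
    resnames = ([solute_resname] if n_sol else []) + ["SOL"] * n_wat
    for el in config.solute_elements:
        names.append(el)
    for i, el in enumerate(config.solvent_elements):
        names.append({"O": "OW", "H": "HW%d" % (i % 3)}[el])
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
    u.add_TopologyAttr(
        "elements",
        list(config.solute_elements) + list(config.solvent_elements))
    pos = np.vstack([config.solute_pos.reshape(-1, 3),
                     config.solvent_pos.reshape(-1, 3)])
    u.atoms.positions = pos
    u.dimensions = [*config.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _resindex(n_sol: int, n_wat: int) -> np.ndarray:
    idx = []
    if n_sol:
        idx.extend([0] * n_sol)
    base = 1 if n_sol else 0
    for w in range(n_wat):
        idx.extend([base + w] * 3)
    return np.asarray(idx)


def write_mesh(surface, path, file_type: str | None = None) -> None:
    """Export a void surface as PLY (binary) or OFF by extension."""
    path = Path(path)
    ft = file_type or path.suffix.lstrip(".").lower()
    surface.mesh.export(str(path), file_type=ft)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
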