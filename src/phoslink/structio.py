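"""Reading and writing structures and ensembles.

PDB input/output goes through :mod:`biotite.structure`; multi-frame
ensembles are written as multi-model PDB files (MODEL/ENDMDL) or
concatenated XYZ blocks.  Atom naming follows carbohydrate convention
(primed names for the glycosylating residue), and the element column is
always populated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .builder import Structure

__all__ = [
    "write_pdb",
    "read_pdb",
    "write_xyz",
    "read_xyz",
]

_RES_NAMES = {
    "Man_nonred": "MAN",
    "Man_red": "MAN",
    "phosphate": "PO4",
    "methyl": "MEO",
}
_RES_NAMES_INV = {v: k for k, v in _RES_NAMES.items()}


_COVALENT_RADII = {"H": 0.31, "C": 0.76, "O": 0.66, "P": 1.07}


def _infer_bonds(coords, elements, tolerance=0.40):
    """Bond pairs by the covalent-radius criterion.

    Two atoms are bonded when their distance is below the sum of their
    covalent radii plus ``tolerance`` angstroms; crosses residue
    boundaries, which distance-based residue-local schemes miss for the
    phosphodiester bridge.
    """
    coords = np.asarray(coords, float)
    radii = np.array([_COVALENT_RADII.get(e, 0.8) for e in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    limit = radii[:, None] + radii[None, :] + tolerance
    a, b = np.where((d < limit) & (d > 0.1))
    return [(int(i), int(j)) for i, j in zip(a, b) if i < j]


def _residue_runs(residues):
    """Consecutive runs of equal residue labels -> sequential res_ids."""
    ids = np.empty(len(residues), dtype=int)
    current = None
    rid = 0
    for i, r in enumerate(residues):
        if r != current:
            rid += 1
            current = r
        ids[i] = rid
    return ids


def _to_atom_array(structure: Structure, coords=None) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, float)
    arr.atom_name = np.asarray(structure.names, dtype="U6")
    arr.element = np.asarray([e.upper() for e in structure.elements], dtype="U2")
    arr.res_name = np.asarray(
        [_RES_NAMES.get(r, r[:3].upper()) for r in structure.residues], dtype="U5"
    )
    arr.res_id = _residue_runs(structure.residues)
    arr.hetero = np.full(n, True)
    arr.chain_id = np.full(n, "A", dtype="U4")
    return arr


def write_pdb(path, structure: Structure, frames: np.ndarray | None = None) -> None:
    """Write a structure (or an ``(F, n, 3)`` frame stack) as PDB.

    With ``frames`` given, a multi-model file is produced, one MODEL per
    frame, all sharing the structure's topology.
    """
    pdb = PDBFile()
    if frames is None:
        pdb.set_structure(_to_atom_array(structure))
    else:
        frames = np.asarray(frames, float)
        template = _to_atom_array(structure)
        stack = struc.from_template(template, frames)
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path) -> tuple[Structure, np.ndarray]:
    """Read a (possibly multi-model) PDB file.

    Returns ``(structure, frames)`` where ``structure`` holds the first
    model and ``frames`` has shape ``(F, n_atoms, 3)``.  Bonds are
    inferred from inter-atomic distances.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    first = stack[0]
    bonds = _infer_bonds(first.coord, [e.capitalize() for e in first.element])
    residues = [
        _RES_NAMES_INV.get(rn, rn) for rn in first.res_name
    ]
    structure = Structure(
        list(first.atom_name),
        [e.capitalize() for e in first.element],
        residues,
        first.coord,
        bonds,
        provenance=f"read_pdb({Path(path).name})",
    )
    return structure, stack.coord.copy()


def write_xyz(path, structure: Structure, frames: np.ndarray | None = None, comment: str = "") -> None:
    """Write XYZ (single block, or concatenated blocks for a frame stack)."""
    frames = structure.coords[None] if frames is None else np.asarray(frames, float)
    with open(path, "w") as fh:
        for f, xyz in enumerate(frames):
            fh.write(f"{len(structure)}\n")
            fh.write(f"{comment or structure.provenance or ''} frame={f}\n")
            for el, p in zip(structure.elements, xyz):
                fh.write(f"{el:2s} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read concatenated XYZ; returns ``(elements, frames)``."""
    frames = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        els = []
        xyz = np.empty((n, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            els.append(parts[0])
            xyz[k] = [float(x) for x in parts[1:4]]
        if not elements:
            elements = els
        frames.append(xyz)
        i += 2 + n
    return elements, np.asarray(frames)
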