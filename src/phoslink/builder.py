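"""Construction of idealised 3D models.

Builds dimethyl phosphate (the symmetric phosphodiester model compound)
and the three phosphodiester-linked dimannosides from internal
coordinates.  Geometry is idealised -- standard bond lengths, tetrahedral
angles and an ideal 4C1 chair -- because the conformational observables
of interest (linker torsions, inter-proton distance statistics) are
controlled by torsion angles, not by fine covalent geometry.

Template constants:

* C-C 1.52 A, C-O 1.43 A, C-H 1.09 A, O-H 0.96 A
* P-O(ester) 1.60 A, P-O(anionic) 1.48 A
* tetrahedral angles 109.47 deg; pyranose ring angles 110.5 deg with
  alternating ring torsions of +/-57.4 deg (the magnitude consistent
  with ring closure at 110.5-deg angles)

Free torsions of a dimannoside are named ``anomeric`` (O5'-C1'-O1'-P),
``zeta1`` (C1'-O1'-P-Ox), ``zeta2`` (Cx-Ox-P-O1'), ``reducing_end``
(P-Ox-Cx-Hx) and, for the 1->6 linkage only, ``omega`` (O5-C5-C6-O6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import geometry as geom
from .rotamers import ConformerSpec, Linkage, DEFAULT_ANOMERIC_TORSION

__all__ = [
    "AtomRecord",
    "Structure",
    "TorsionDefinition",
    "ZMatrixEntry",
    "InternalCoordinateTemplate",
    "place_atoms",
    "dimethyl_phosphate_template",
    "build_dimethyl_phosphate",
    "build_mannose",
    "build_disaccharide",
    "assemble_disaccharide_frames",
    "disaccharide_torsion_definitions",
    "free_torsion_labels",
    "BOND_LENGTHS",
    "TETRAHEDRAL_ANGLE",
]

BOND_LENGTHS = {
    "CC": 1.52,
    "CO": 1.43,
    "CH": 1.09,
    "OH": 0.96,
    "PO_ester": 1.60,
    "PO_anionic": 1.48,
}

TETRAHEDRAL_ANGLE = 109.47122
RING_ANGLE = 110.5
# Magnitude of the alternating chair torsion consistent with closure at
# 110.5-deg ring angles: cos(tau) = -cos(theta) / (1 + cos(theta)).
RING_TORSION = math.degrees(
    math.acos(-math.cos(math.radians(RING_ANGLE)) / (1.0 + math.cos(math.radians(RING_ANGLE))))
)
ESTER_ANGLE = 120.0  # C-O-P and P-O-C ester angles


@dataclass(frozen=True)
class TorsionDefinition:
    """Four ordered atom names defining a signed dihedral."""

    atoms: tuple[str, str, str, str]
    label: str = ""

    def __post_init__(self):
        if len(set(self.atoms)) != 4:
            raise ValueError(f"torsion atoms must be distinct, got {self.atoms}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, residue membership and position (A)."""

    name: str
    element: str
    residue_id: str
    position: np.ndarray


class Structure:
    """An ordered collection of atoms with bonds and provenance.

    Atom names are unique across the structure; atoms of the
    glycosylating (non-reducing) mannose carry primed names (C1', H1',
    ...), following carbohydrate convention.
    """

    def __init__(self, names, elements, residues, coords, bonds, provenance=None):
        self.names = list(names)
        self.elements = list(elements)
        self.residues = list(residues)
        self.coords = np.asarray(coords, dtype=float).reshape(len(self.names), 3)
        self.bonds = sorted({tuple(sorted(b)) for b in bonds})
        self.provenance = provenance
        if len(set(self.names)) != len(self.names):
            raise ValueError("atom names must be unique within a structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(n, e, r, self.coords[i].copy())
            for i, (n, e, r) in enumerate(zip(self.names, self.elements, self.residues))
        ]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no atom named {name!r}; available: {sorted(self._index)}") from None

    def position(self, name: str) -> np.ndarray:
        return self.coords[self.index(name)]

    def measure_distance(self, a: str, b: str) -> float:
        return geom.distance(self.position(a), self.position(b))

    def measure_angle(self, a: str, b: str, c: str) -> float:
        return geom.bond_angle(self.position(a), self.position(b), self.position(c))

    def measure_torsion(self, torsion: "TorsionDefinition | Sequence[str]") -> float:
        names = torsion.atoms if isinstance(torsion, TorsionDefinition) else tuple(torsion)
        if len(names) != 4:
            raise ValueError("a torsion needs exactly four atom names")
        p = [self.position(n) for n in names]
        return geom.dihedral(*p)

    def drop(self, names: Iterable[str]) -> "Structure":
        """A copy of the structure without the given atoms."""
        gone = set(names)
        keep = [i for i, n in enumerate(self.names) if n not in gone]
        remap = {old: new for new, old in enumerate(keep)}
        bonds = [
            (remap[a], remap[b]) for a, b in self.bonds if a in remap and b in remap
        ]
        return Structure(
            [self.names[i] for i in keep],
            [self.elements[i] for i in keep],
            [self.residues[i] for i in keep],
            self.coords[keep],
            bonds,
            provenance=self.provenance,
        )

    def transformed(self, rotation=None, translation=None) -> "Structure":
        """A rigidly moved copy (rotation matrix applied first)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, float).T
        if translation is not None:
            coords = coords + np.asarray(translation, float)
        return Structure(
            self.names, self.elements, self.residues, coords, self.bonds, self.provenance
        )

    def bonded_neighbors(self, name: str) -> list[str]:
        i = self.index(name)
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(self.names[b])
            elif b == i:
                out.append(self.names[a])
        return out


# ---------------------------------------------------------------------------
# Z-matrix engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZMatrixEntry:
    """One internal-coordinate atom placement.

    ``refs`` are up to three previously placed atom names (distance,
    angle, torsion references in that order).  ``torsion`` is either a
    number (degrees) or a free-torsion label, optionally with a constant
    offset, as ``(label, offset)``.
    """

    name: str
    element: str
    residue_id: str
    refs: tuple[str, ...] = ()
    dist: float | None = None
    angle: float | None = None
    torsion: "float | str | tuple[str, float] | None" = None


@dataclass(frozen=True)
class InternalCoordinateTemplate:
    """An ordered Z-matrix with named free torsions."""

    entries: tuple[ZMatrixEntry, ...]
    free_torsions: tuple[str, ...]
    torsion_definitions: Mapping[str, TorsionDefinition] = field(default_factory=dict)
    extra_bonds: tuple[tuple[str, str], ...] = ()
    tag: str = ""

    def __post_init__(self):
        placed = set()
        for e in self.entries:
            for r in e.refs:
                if r not in placed:
                    raise ValueError(
                        f"entry {e.name!r} references unplaced atom {r!r}"
                    )
            placed.add(e.name)


def _resolve_torsion(torsion, free: Mapping[str, np.ndarray]):
    if isinstance(torsion, str):
        return free[torsion]
    if isinstance(torsion, tuple):
        label, offset = torsion
        return free[label] + offset
    return torsion


def place_atoms(
    template: InternalCoordinateTemplate,
    free_torsions: Mapping[str, float] | None = None,
    provenance=None,
) -> Structure:
    """Convert a Z-matrix template to a Cartesian :class:`Structure`.

    All named free torsions must be supplied (no partial defaults) unless
    the template names none.
    """
    free = dict(free_torsions or {})
    missing = [l for l in template.free_torsions if l not in free]
    if missing:
        raise ValueError(f"missing free torsions: {missing}")
    coords = _place_zmatrix(template, {k: np.asarray(v, float) for k, v in free.items()})
    names = [e.name for e in template.entries]
    idx = {n: i for i, n in enumerate(names)}
    bonds = [(idx[e.refs[0]], idx[e.name]) for e in template.entries if e.refs]
    bonds += [(idx[a], idx[b]) for a, b in template.extra_bonds]
    return Structure(
        names,
        [e.element for e in template.entries],
        [e.residue_id for e in template.entries],
        coords,
        bonds,
        provenance=provenance if provenance is not None else template.tag,
    )


def _place_zmatrix(template: InternalCoordinateTemplate, free) -> np.ndarray:
    """Core NeRF loop; returns an (n_atoms, 3) array."""
    pos: dict[str, np.ndarray] = {}
    out = []
    for i, e in enumerate(template.entries):
        if len(e.refs) == 0:
            p = np.zeros(3)
        elif len(e.refs) == 1:
            p = pos[e.refs[0]] + np.array([e.dist, 0.0, 0.0])
        elif len(e.refs) == 2:
            b, a = pos[e.refs[0]], pos[e.refs[1]]
            u = (a - b) / np.linalg.norm(a - b)
            theta = math.radians(e.angle)
            # any in-plane perpendicular; anchors live in the xy plane
            perp = np.array([-u[1], u[0], 0.0])
            n = np.linalg.norm(perp)
            if n < 1e-9:
                perp = np.array([0.0, 1.0, 0.0])
            else:
                perp = perp / n
            p = b + e.dist * (u * math.cos(theta) + perp * math.sin(theta))
        else:
            c, b, a = (pos[r] for r in e.refs)
            tor = _resolve_torsion(e.torsion, free)
            p = geom.nerf_place(a, b, c, e.dist, e.angle, tor)
        pos[e.name] = p
        out.append(p)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Dimethyl phosphate
# ---------------------------------------------------------------------------


def dimethyl_phosphate_template() -> InternalCoordinateTemplate:
    """Z-matrix for dimethyl phosphate with free zeta1/zeta2 torsions.

    zeta1 = CA-OA-P-OB (torsion about the OA-P ester bond),
    zeta2 = CB-OB-P-OA (torsion about the OB-P ester bond).
    """
    L = BOND_LENGTHS
    T = TETRAHEDRAL_ANGLE
    e = [
        ZMatrixEntry("CA", "C", "methyl"),
        ZMatrixEntry("OA", "O", "phosphate", ("CA",), L["CO"]),
        ZMatrixEntry("P", "P", "phosphate", ("OA", "CA"), L["PO_ester"], ESTER_ANGLE),
        ZMatrixEntry("OB", "O", "phosphate", ("P", "OA", "CA"), L["PO_ester"], T, "zeta1"),
        ZMatrixEntry("OP1", "O", "phosphate", ("P", "OA", "CA"), L["PO_anionic"], T, ("zeta1", 120.0)),
        ZMatrixEntry("OP2", "O", "phosphate", ("P", "OA", "CA"), L["PO_anionic"], T, ("zeta1", -120.0)),
        ZMatrixEntry("CB", "C", "methyl", ("OB", "P", "OA"), L["CO"], ESTER_ANGLE, "zeta2"),
        ZMatrixEntry("HA1", "H", "methyl", ("CA", "OA", "P"), L["CH"], T, 180.0),
        ZMatrixEntry("HA2", "H", "methyl", ("CA", "OA", "P"), L["CH"], T, 60.0),
        ZMatrixEntry("HA3", "H", "methyl", ("CA", "OA", "P"), L["CH"], T, -60.0),
        ZMatrixEntry("HB1", "H", "methyl", ("CB", "OB", "P"), L["CH"], T, 180.0),
        ZMatrixEntry("HB2", "H", "methyl", ("CB", "OB", "P"), L["CH"], T, 60.0),
        ZMatrixEntry("HB3", "H", "methyl", ("CB", "OB", "P"), L["CH"], T, -60.0),
    ]
    tdefs = {
        "zeta1": TorsionDefinition(("CA", "OA", "P", "OB"), "zeta1"),
        "zeta2": TorsionDefinition(("CB", "OB", "P", "OA"), "zeta2"),
    }
    return InternalCoordinateTemplate(
        tuple(e), ("zeta1", "zeta2"), tdefs, tag="dimethyl_phosphate"
    )


def build_dimethyl_phosphate(zeta1: float, zeta2: float) -> Structure:
    """Build dimethyl phosphate with the given ester torsions (degrees)."""
    return place_atoms(
        dimethyl_phosphate_template(),
        {"zeta1": zeta1, "zeta2": zeta2},
        provenance=f"dimethyl_phosphate(zeta1={zeta1:g}, zeta2={zeta2:g})",
    )


# ---------------------------------------------------------------------------
# alpha-D-mannopyranose residue
# ---------------------------------------------------------------------------

# Axial/equatorial substituent pattern of alpha-D-mannopyranose in the
# 4C1 chair: anomeric O1 and the manno O2 are axial, O3/O4 and the
# hydroxymethyl C6 are equatorial.
_SUBSTITUENTS = {
    # ring atom: (axial atom, element, dist key), (equatorial atom, ...)
    "C1": (("O1", "O", "CO"), ("H1", "H", "CH")),
    "C2": (("O2", "O", "CO"), ("H2", "H", "CH")),
    "C3": (("H3", "H", "CH"), ("O3", "O", "CO")),
    "C4": (("H4", "H", "CH"), ("O4", "O", "CO")),
    "C5": (("H5", "H", "CH"), ("C6", "C", "CC")),
}

# Ring torsion sign pattern for the 4C1 chair of a D-pyranose under the
# IUPAC dihedral convention: C1-C2-C3-C4 is negative (about -57 deg),
# O5-C1-C2-C3 positive, alternating around the ring.
_RING_SIGN = -1.0


@lru_cache(maxsize=None)
def _mannose_canonical(primed: bool, aglycon: str) -> Structure:
    """Canonical alpha-D-mannopyranose residue in its own frame.

    ``aglycon`` is ``"OH"`` (free anomeric hydroxyl) or ``"OMe"`` (methyl
    glycoside).  The residue is complete, including all hydroxyl protons;
    assembly into a disaccharide drops the proton of whichever oxygen
    becomes an ester.
    """
    L = BOND_LENGTHS
    T = TETRAHEDRAL_ANGLE
    s = _RING_SIGN
    tau = RING_TORSION

    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    idx: dict[str, int] = {}

    def add(name, element, pos, parent=None):
        idx[name] = len(names)
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(pos, float))
        if parent is not None:
            bonds.append((idx[parent], idx[name]))

    # -- ring: C1 C2 C3 C4 C5 O5 in an ideal chair -------------------------
    add("C1", "C", (0.0, 0.0, 0.0))
    add("C2", "C", (L["CC"], 0.0, 0.0), "C1")
    theta = math.radians(RING_ANGLE)
    add(
        "C3",
        "C",
        coords[idx["C2"]] + L["CC"] * np.array([-math.cos(theta), math.sin(theta), 0.0]),
        "C2",
    )
    add(
        "C4",
        "C",
        geom.nerf_place(coords[idx["C1"]], coords[idx["C2"]], coords[idx["C3"]],
                        L["CC"], RING_ANGLE, s * tau),
        "C3",
    )
    add(
        "C5",
        "C",
        geom.nerf_place(coords[idx["C2"]], coords[idx["C3"]], coords[idx["C4"]],
                        L["CC"], RING_ANGLE, -s * tau),
        "C4",
    )
    add(
        "O5",
        "O",
        geom.nerf_place(coords[idx["C3"]], coords[idx["C4"]], coords[idx["C5"]],
                        L["CO"], RING_ANGLE, s * tau),
        "C5",
    )
    bonds.append((idx["O5"], idx["C1"]))  # ring closure

    ring = ["C1", "C2", "C3", "C4", "C5", "O5"]
    ring_xyz = np.array([coords[idx[n]] for n in ring])
    centroid = ring_xyz.mean(axis=0)
    rel = ring_xyz - centroid
    normal = np.zeros(3)
    for i in range(6):
        normal += np.cross(rel[i], rel[(i + 1) % 6])
    normal /= np.linalg.norm(normal)

    # -- ring substituents via tetrahedral completion ----------------------
    neighbors = {"C1": ("O5", "C2"), "C2": ("C1", "C3"), "C3": ("C2", "C4"),
                 "C4": ("C3", "C5"), "C5": ("C4", "O5")}
    for carbon, ((ax_name, ax_el, ax_key), (eq_name, eq_el, eq_key)) in _SUBSTITUENTS.items():
        c = coords[idx[carbon]]
        nb1, nb2 = (coords[idx[n]] for n in neighbors[carbon])
        d1, d2 = geom.tetrahedral_completions(c, nb1, nb2)
        # the completion more nearly parallel to the ring normal is axial
        if abs(float(np.dot(d1, normal))) >= abs(float(np.dot(d2, normal))):
            ax_dir, eq_dir = d1, d2
        else:
            ax_dir, eq_dir = d2, d1
        add(ax_name, ax_el, c + L[ax_key] * ax_dir, carbon)
        add(eq_name, eq_el, c + L[eq_key] * eq_dir, carbon)

    def nerf(a, b, c, dist, angle, torsion):
        return geom.nerf_place(coords[idx[a]], coords[idx[b]], coords[idx[c]], dist, angle, torsion)

    # -- anomeric substituent: free OH or methyl glycoside -----------------
    # staggered default torsions; they enter no reported observable
    if aglycon == "OMe":
        add("CM", "C", nerf("O5", "C1", "O1", L["CO"], T, 60.0), "O1")
        add("HM1", "H", nerf("C1", "O1", "CM", L["CH"], T, 180.0), "CM")
        add("HM2", "H", nerf("C1", "O1", "CM", L["CH"], T, 60.0), "CM")
        add("HM3", "H", nerf("C1", "O1", "CM", L["CH"], T, -60.0), "CM")
    else:
        add("HO1", "H", nerf("O5", "C1", "O1", L["OH"], T, 60.0), "O1")

    # -- remaining hydroxyls, anti to the ring proton ----------------------
    add("HO2", "H", nerf("H2", "C2", "O2", L["OH"], T, 180.0), "O2")
    add("HO3", "H", nerf("H3", "C3", "O3", L["OH"], T, 180.0), "O3")
    add("HO4", "H", nerf("H4", "C4", "O4", L["OH"], T, 180.0), "O4")

    # -- hydroxymethyl arm: O6 at the gg well (omega = O5-C5-C6-O6 = -60) --
    add("O6", "O", nerf("O5", "C5", "C6", L["CO"], T, -60.0), "C6")
    h1, h2 = geom.tetrahedral_completions(
        coords[idx["C6"]], coords[idx["C5"]], coords[idx["O6"]]
    )
    c6 = coords[idx["C6"]]
    add("H6a", "H", c6 + L["CH"] * h1, "C6")
    add("H6b", "H", c6 + L["CH"] * h2, "C6")
    add("HO6", "H", nerf("C5", "C6", "O6", L["OH"], T, 180.0), "O6")

    if primed:
        names = [n + "'" for n in names]
    residue = "Man_nonred" if primed else "Man_red"
    return Structure(
        names,
        elements,
        [residue] * len(names),
        np.asarray(coords),
        bonds,
        provenance=f"alpha-D-mannopyranose({'primed' if primed else 'reducing'}, {aglycon})",
    )


def build_mannose(primed: bool = False, aglycon: str = "OH") -> Structure:
    """A standalone idealised alpha-D-mannopyranose residue.

    ``primed=True`` yields the glycosylating residue with primed atom
    names; ``aglycon`` selects a free anomeric hydroxyl (``"OH"``) or a
    methyl glycoside (``"OMe"``).
    """
    if aglycon not in ("OH", "OMe"):
        raise ValueError("aglycon must be 'OH' or 'OMe'")
    return _mannose_canonical(primed, aglycon)


# ---------------------------------------------------------------------------
# Disaccharide assembly
# ---------------------------------------------------------------------------


def free_torsion_labels(linkage: "Linkage | str | int") -> tuple[str, ...]:
    """Free torsion labels of a dimannoside with the given linkage."""
    linkage = Linkage.coerce(linkage)
    labels = ("anomeric", "zeta1", "zeta2", "reducing_end")
    if linkage is Linkage.ONE_SIX:
        labels = labels + ("omega",)
    return labels


def disaccharide_torsion_definitions(linkage: "Linkage | str | int") -> dict[str, TorsionDefinition]:
    """Named torsion definitions (atom quadruples) for one linkage."""
    linkage = Linkage.coerce(linkage)
    x = linkage.position
    ox, cx = f"O{x}", f"C{x}"
    hx = "H6a" if x == 6 else f"H{x}"
    defs = {
        "anomeric": TorsionDefinition(("O5'", "C1'", "O1'", "P"), "anomeric"),
        "zeta1": TorsionDefinition(("C1'", "O1'", "P", ox), "zeta1"),
        "zeta2": TorsionDefinition((cx, ox, "P", "O1'"), "zeta2"),
        "reducing_end": TorsionDefinition(("P", ox, cx, hx), "reducing_end"),
    }
    if x == 6:
        defs["omega"] = TorsionDefinition(("O5", "C5", "C6", "O6"), "omega")
    return defs


#: Default omega (O5-C5-C6-O6) torsion for single-structure builds of the
#: 1->6 compound: the gg well.
DEFAULT_OMEGA = -60.0


def _triad_rotation(canon_triad: np.ndarray, target_triad: np.ndarray):
    """Rotation + translation mapping a canonical 3-point triad onto targets.

    ``canon_triad`` is (3, 3); ``target_triad`` broadcasts as (..., 3, 3)
    with the three points along axis -2.  Returns (R, t) so that
    x -> x @ R.T + t maps canonical coordinates into the target frame.
    """
    fc = geom.triad_frame(canon_triad[0], canon_triad[1], canon_triad[2])
    ft = geom.triad_frame(
        target_triad[..., 0, :], target_triad[..., 1, :], target_triad[..., 2, :]
    )
    rot = ft @ fc.T
    trans = target_triad[..., 0, :] - np.squeeze(rot @ canon_triad[0][:, None], -1)
    return rot, trans


def assemble_disaccharide_frames(
    linkage: "Linkage | str | int",
    torsions: Mapping[str, "float | np.ndarray"],
    provenance=None,
) -> tuple[Structure, np.ndarray]:
    """Build one or many dimannoside geometries sharing one topology.

    ``torsions`` maps each free torsion label (see
    :func:`free_torsion_labels`) to a scalar or a length-F array of
    values in degrees.  Returns ``(topology, coords)`` where ``topology``
    is a :class:`Structure` holding frame 0 and ``coords`` has shape
    ``(F, n_atoms, 3)``.  Broadcasting over frames is fully vectorised,
    which is what makes ensemble realisation cheap.
    """
    linkage = Linkage.coerce(linkage)
    x = linkage.position
    labels = free_torsion_labels(linkage)
    missing = [l for l in labels if l not in torsions]
    if missing:
        raise ValueError(f"missing torsion labels for {linkage.value}: {missing}")
    vals = {k: np.atleast_1d(np.asarray(torsions[k], float)) for k in labels}
    F = max(v.shape[0] for v in vals.values())
    for k, v in vals.items():
        if v.shape[0] not in (1, F):
            raise ValueError("torsion arrays must share a common frame count")
        vals[k] = np.broadcast_to(v, (F,))

    L = BOND_LENGTHS
    T = TETRAHEDRAL_ANGLE

    glyco = _mannose_canonical(True, "OH").drop(["HO1'"])
    red_full = _mannose_canonical(False, "OMe")
    ox, cx = f"O{x}", f"C{x}"
    hx = "H6a" if x == 6 else f"H{x}"
    red = red_full.drop([f"HO{x}"])

    n_g = len(glyco)
    names = list(glyco.names) + ["P", "OP1", "OP2"] + list(red.names)
    elements = list(glyco.elements) + ["P", "O", "O"] + list(red.elements)
    residues = list(glyco.residues) + ["phosphate"] * 3 + list(red.residues)
    coords = np.empty((F, len(names), 3))
    coords[:, :n_g] = glyco.coords[None, :, :]
    col = {n: i for i, n in enumerate(names)}

    def g(name):
        return np.broadcast_to(glyco.position(name), (F, 3))

    # phosphate group off the glycosylating anomeric oxygen
    p_pos = geom.nerf_place(g("O5'"), g("C1'"), g("O1'"),
                            L["PO_ester"], ESTER_ANGLE, vals["anomeric"])
    ox_pos = geom.nerf_place(g("C1'"), g("O1'"), p_pos,
                             L["PO_ester"], T, vals["zeta1"])
    op1 = geom.nerf_place(g("C1'"), g("O1'"), p_pos,
                          L["PO_anionic"], T, vals["zeta1"] + 120.0)
    op2 = geom.nerf_place(g("C1'"), g("O1'"), p_pos,
                          L["PO_anionic"], T, vals["zeta1"] - 120.0)
    coords[:, col["P"]] = p_pos
    coords[:, col["OP1"]] = op1
    coords[:, col["OP2"]] = op2

    # bridge carbon and the rotamer-defining proton of the reducing residue
    d_oc = red_full.measure_distance(ox, cx)
    cx_pos = geom.nerf_place(g("O1'"), p_pos, ox_pos, d_oc, ESTER_ANGLE, vals["zeta2"])
    d_ch = red_full.measure_distance(cx, hx)
    a_hco = red_full.measure_angle(hx, cx, ox)
    hx_pos = geom.nerf_place(p_pos, ox_pos, cx_pos, d_ch, a_hco, vals["reducing_end"])

    red_cols = {n: col[n] for n in red.names}
    coords[:, red_cols[ox]] = ox_pos
    coords[:, red_cols[cx]] = cx_pos
    coords[:, red_cols[hx]] = hx_pos

    if x != 6:
        # the whole residue is rigid relative to the (Ox, Cx, Hx) anchor
        canon = np.array([red_full.position(ox), red_full.position(cx), red_full.position(hx)])
        target = np.stack([ox_pos, cx_pos, hx_pos], axis=-2)
        rot, trans = _triad_rotation(canon, target)
        rest = [n for n in red.names if n not in (ox, cx, hx)]
        block = np.array([red_full.position(n) for n in rest])
        mapped = np.einsum("fij,nj->fni", rot, block) + trans[:, None, :]
        for k, n in enumerate(rest):
            coords[:, red_cols[n]] = mapped[:, k]
    else:
        # 1->6: the exocyclic arm (H6b, C5) follows the reducing-end
        # rotamer; the ring block then rotates about C5-C6 with omega.
        def offset(a_name, ref_name):
            # torsion offset of a_name vs ref_name about the O6-C6 bond
            return geom.normalize_angle(
                red_full.measure_torsion((a_name, "C6", "O6", "HO6"))
                - red_full.measure_torsion((ref_name, "C6", "O6", "HO6"))
            )

        d_h6b = red_full.measure_distance("C6", "H6b")
        a_h6b = red_full.measure_angle("H6b", "C6", "O6")
        h6b_pos = geom.nerf_place(
            p_pos, ox_pos, cx_pos, d_h6b, a_h6b,
            vals["reducing_end"] + offset("H6b", "H6a"),
        )
        d_c5 = red_full.measure_distance("C6", "C5")
        a_c5 = red_full.measure_angle("C5", "C6", "O6")
        c5_pos = geom.nerf_place(
            p_pos, ox_pos, cx_pos, d_c5, a_c5,
            vals["reducing_end"] + offset("C5", "H6a"),
        )
        # place C4 about the C5-C6 bond; omega is defined on O5, so shift
        # by the canonical C4-vs-O5 offset about that bond
        delta_c4 = geom.normalize_angle(
            red_full.measure_torsion(("O6", "C6", "C5", "C4"))
            - red_full.measure_torsion(("O6", "C6", "C5", "O5"))
        )
        d_c4 = red_full.measure_distance("C5", "C4")
        a_c4 = red_full.measure_angle("C4", "C5", "C6")
        c4_pos = geom.nerf_place(
            ox_pos, cx_pos, c5_pos, d_c4, a_c4, vals["omega"] + delta_c4
        )
        coords[:, red_cols["H6b"]] = h6b_pos
        coords[:, red_cols["C5"]] = c5_pos
        coords[:, red_cols["C4"]] = c4_pos
        canon = np.array([red_full.position("C4"), red_full.position("C5"), red_full.position("C6")])
        target = np.stack([c4_pos, c5_pos, cx_pos], axis=-2)
        rot, trans = _triad_rotation(canon, target)
        done = {ox, cx, hx, "H6b", "C5", "C4"}
        rest = [n for n in red.names if n not in done]
        block = np.array([red_full.position(n) for n in rest])
        mapped = np.einsum("fij,nj->fni", rot, block) + trans[:, None, :]
        for k, n in enumerate(rest):
            coords[:, red_cols[n]] = mapped[:, k]

    # bond list: both residues plus the four P-O bonds
    bonds = list(glyco.bonds)
    bonds.append((col["O1'"], col["P"]))
    bonds.append((col["P"], col["OP1"]))
    bonds.append((col["P"], col["OP2"]))
    bonds.append((col["P"], col[ox]))
    shift = {red.index(n): col[n] for n in red.names}
    bonds += [(shift[a], shift[b]) for a, b in red.bonds]

    topology = Structure(
        names, elements, residues, coords[0], bonds, provenance=provenance
    )
    return topology, coords


def build_disaccharide(spec: ConformerSpec, **torsion_overrides) -> Structure:
    """Build one dimannoside model from a :class:`ConformerSpec`.

    The linker torsions come from the spec's rotamer states (well-center
    values); keyword overrides allow exact angles, e.g. ``omega=-60``.
    """
    if not isinstance(spec, ConformerSpec):
        raise TypeError("build_disaccharide expects a ConformerSpec")
    torsions = {
        "anomeric": spec.anomeric_torsion,
        "zeta1": spec.linker.zeta1.center_angle,
        "zeta2": spec.linker.zeta2.center_angle,
        "reducing_end": spec.reducing_end_rotamer,
    }
    if spec.linkage is Linkage.ONE_SIX:
        torsions["omega"] = DEFAULT_OMEGA
    torsions.update(torsion_overrides)
    topology, coords = assemble_disaccharide_frames(spec.linkage, torsions, provenance=spec)
    return Structure(
        topology.names,
        topology.elements,
        topology.residues,
        coords[0],
        topology.bonds,
        provenance=spec,
    )
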