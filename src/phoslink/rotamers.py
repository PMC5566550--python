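"""Symbolic rotamer algebra for the phosphodiester linker.

A phosphodiester bridge -O-PO2(-)-O- has two ester C-O-P-O torsions
(zeta1, zeta2 here), each of which occupies one of the three staggered
wells gauche+ (+60 deg), gauche- (-60 deg) or trans (180 deg).  This
module enumerates the well combinations, applies the mixed-gauche
exclusion (a g+/g- pairing collapses during optimisation because of
oxygen-oxygen repulsion and is therefore never a stable linker
conformer), reduces symmetric diesters such as dimethyl phosphate by
exchange symmetry of the two arms, and expands linker conformers into
full starting-conformation specifications for the three dimannosides.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "RotamerState",
    "LinkerConformer",
    "ConformerSpec",
    "Linkage",
    "CANONICAL_STATES",
    "enumerate_state_pairs",
    "enumerate_linker_conformers",
    "enumerate_starting_conformers",
    "classify_rotamer",
    "conformers_to_csv",
    "REDUCING_END_ROTAMERS",
    "DEFAULT_ANOMERIC_TORSION",
]

# The exo-anomeric effect holds the O5'-C1'-O1'-P torsion of an
# alpha-glycosyl phosphate in the gauche well; +60 deg is the standard
# starting value for this torsion.
DEFAULT_ANOMERIC_TORSION = 60.0

# P-Ox-Cx-Hx rotamer wells available to the phosphorylated (reducing-end)
# residue: +/-60 or 180 degrees.
REDUCING_END_ROTAMERS = (60.0, -60.0, 180.0)


class RotamerState(enum.Enum):
    """One staggered well of a rotatable bond."""

    GAUCHE_PLUS = "g+"
    GAUCHE_MINUS = "g-"
    TRANS = "t"

    @property
    def center_angle(self) -> float:
        """Well-center torsion value in degrees."""
        return _CENTER_ANGLES[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CENTER_ANGLES = {
    RotamerState.GAUCHE_PLUS: 60.0,
    RotamerState.GAUCHE_MINUS: -60.0,
    RotamerState.TRANS: 180.0,
}

#: Canonical ordering g+ < g- < t used for deterministic enumeration and
#: for the canonical form of exchange-symmetric pairs.
CANONICAL_STATES = (
    RotamerState.GAUCHE_PLUS,
    RotamerState.GAUCHE_MINUS,
    RotamerState.TRANS,
)

_STATE_RANK = {s: i for i, s in enumerate(CANONICAL_STATES)}


class Linkage(enum.Enum):
    """Position of the phosphodiester on the reducing-end mannose."""

    ONE_THREE = "1->3"
    ONE_FOUR = "1->4"
    ONE_SIX = "1->6"

    @property
    def position(self) -> int:
        """The substituted carbon number (3, 4 or 6)."""
        return {"1->3": 3, "1->4": 4, "1->6": 6}[self.value]

    @classmethod
    def coerce(cls, value: "Linkage | str | int") -> "Linkage":
        if isinstance(value, Linkage):
            return value
        aliases = {
            "1->3": cls.ONE_THREE, "1-3": cls.ONE_THREE, "13": cls.ONE_THREE,
            "3": cls.ONE_THREE, 3: cls.ONE_THREE,
            "1->4": cls.ONE_FOUR, "1-4": cls.ONE_FOUR, "14": cls.ONE_FOUR,
            "4": cls.ONE_FOUR, 4: cls.ONE_FOUR,
            "1->6": cls.ONE_SIX, "1-6": cls.ONE_SIX, "16": cls.ONE_SIX,
            "6": cls.ONE_SIX, 6: cls.ONE_SIX,
        }
        key = value.strip() if isinstance(value, str) else value
        try:
            return aliases[key]
        except KeyError:
            valid = sorted({v.value for v in cls})
            raise ValueError(f"unknown linkage {value!r}; valid linkages: {valid}") from None


@dataclass(frozen=True)
class LinkerConformer:
    """A pairing of the two ester torsion states of a phosphodiester.

    ``symmetric_context`` marks diesters whose two arms are chemically
    equivalent (dimethyl phosphate); such conformers are stored in
    canonical order (lexicographically smaller of the two orderings under
    g+ < g- < t) so that exchange-equivalent pairs compare equal.
    """

    zeta1: RotamerState
    zeta2: RotamerState
    symmetric_context: bool = False

    def __post_init__(self):
        if self.symmetric_context:
            a, b = self.zeta1, self.zeta2
            if _STATE_RANK[b] < _STATE_RANK[a]:
                object.__setattr__(self, "zeta1", b)
                object.__setattr__(self, "zeta2", a)

    @property
    def label(self) -> str:
        return f"{self.zeta1.value}{self.zeta2.value}"

    def is_mixed_gauche(self) -> bool:
        """True for the excluded {g+, g-} pairing (either order)."""
        pair = {self.zeta1, self.zeta2}
        return pair == {RotamerState.GAUCHE_PLUS, RotamerState.GAUCHE_MINUS}


@dataclass(frozen=True)
class ConformerSpec:
    """One fully specified starting conformation of a dimannoside.

    ``reducing_end_rotamer`` is the P-Ox-Cx-Hx torsion of the
    phosphorylated residue (x = 3, 4 or 6 according to the linkage);
    ``anomeric_torsion`` is the O5'-C1'-O1'-P torsion of the
    glycosylating residue, +60 deg by default (exo-anomeric well).
    """

    linkage: Linkage
    linker: LinkerConformer
    reducing_end_rotamer: float
    anomeric_torsion: float = DEFAULT_ANOMERIC_TORSION

    def __post_init__(self):
        object.__setattr__(self, "linkage", Linkage.coerce(self.linkage))
        if self.reducing_end_rotamer not in REDUCING_END_ROTAMERS:
            raise ValueError(
                f"reducing_end_rotamer must be one of {REDUCING_END_ROTAMERS}, "
                f"got {self.reducing_end_rotamer!r}"
            )

    @property
    def compound(self) -> int:
        """Compound number 1/2/3 for the 1->3, 1->4, 1->6 linkage."""
        return {3: 1, 4: 2, 6: 3}[self.linkage.position]


def enumerate_state_pairs() -> list[tuple[RotamerState, RotamerState]]:
    """All nine ordered pairs of rotamer states, in canonical order."""
    return [(a, b) for a in CANONICAL_STATES for b in CANONICAL_STATES]


def enumerate_linker_conformers(
    symmetric: bool, *, exclude_mixed_gauche: bool = True
) -> list[LinkerConformer]:
    """Enumerate stable phosphodiester linker conformers.

    With ``symmetric=True`` (dimethyl phosphate), exchange-equivalent
    pairs are merged, giving five conformers after the mixed-gauche
    exclusion; with ``symmetric=False`` (two inequivalent sugar arms) the
    orders are distinct and seven conformers remain.
    """
    seen: list[LinkerConformer] = []
    for a, b in enumerate_state_pairs():
        conf = LinkerConformer(a, b, symmetric_context=symmetric)
        if exclude_mixed_gauche and conf.is_mixed_gauche():
            continue
        if conf not in seen:
            seen.append(conf)
    return seen


def enumerate_starting_conformers(linkage: "Linkage | str | int") -> list[ConformerSpec]:
    """The full starting-conformer set for one dimannoside.

    Cartesian product of the seven asymmetric linker conformers with the
    three reducing-end rotamers: 21 starting conformations, each with the
    anomeric torsion at its exo-anomeric default of +60 deg.
    """
    linkage = Linkage.coerce(linkage)
    specs = []
    for linker in enumerate_linker_conformers(symmetric=False):
        for rot in REDUCING_END_ROTAMERS:
            specs.append(ConformerSpec(linkage=linkage, linker=linker, reducing_end_rotamer=rot))
    return specs


def classify_rotamer(angle: float) -> RotamerState:
    """Assign a torsion angle (degrees) to its staggered well.

    Windows are three equal 120-degree bins centered on the wells:
    g+ = (0, 120), g- = (-120, 0], trans = the remainder, so the
    boundaries classify as 120 -> trans, 0 -> g-, -120 -> trans.  The
    angle is normalised to (-180, 180] first.
    """
    if not math.isfinite(angle):
        raise ValueError(f"cannot classify non-finite angle {angle!r}")
    from .geometry import normalize_angle

    a = normalize_angle(angle)
    if 0.0 < a < 120.0:
        return RotamerState.GAUCHE_PLUS
    if -120.0 < a <= 0.0:
        return RotamerState.GAUCHE_MINUS
    return RotamerState.TRANS


def conformers_to_csv(specs: Sequence[ConformerSpec]) -> str:
    """Serialise ConformerSpecs to CSV text.

    Columns: linkage, zeta1, zeta2, reducing_end_rotamer, anomeric_torsion.
    """
    buf = io.StringIO()
    buf.write("linkage,zeta1,zeta2,reducing_end_rotamer,anomeric_torsion\n")
    for s in specs:
        buf.write(
            f"{s.linkage.value},{s.linker.zeta1.value},{s.linker.zeta2.value},"
            f"{s.reducing_end_rotamer:g},{s.anomeric_torsion:g}\n"
        )
    return buf.getvalue()
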