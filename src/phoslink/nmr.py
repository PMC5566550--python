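"""NMR observables from ensemble geometry.

Three-bond 31P scalar couplings follow Karplus-type equations
``J(phi) = A cos^2 phi + B cos phi + C`` with the parameterisations

* C-C-O-P:  3J = 6.9 cos^2 phi - 3.4 cos phi + 0.7   (Hz)
* H-C-O-P:  3J = 15.3 cos^2 phi - 6.1 cos phi + 1.6  (Hz)

evaluated frame by frame and then arithmetically averaged -- the
ensemble average of J, never J of the average angle, since the Karplus
curve is strongly non-linear.  (The H-C-O-P set was parameterised on
nucleotides and is known to overestimate sugar-phosphate couplings by
upwards of 1 Hz; it is applied here as-is.)

NOE predictions use the r^-6-effective inter-proton distance: an effect
is considered detectable below a 4.5-A cutoff (strict), and relative
NOE intensities scale as ``(d_ref / d)^6`` against the intra-residue
H1'-H2' reference pair (about 2.6 A in the 4C1 chair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import DistanceSummary, TorsionSummary
from .builder import TorsionDefinition

__all__ = [
    "KarplusCoefficients",
    "CCOP",
    "HCOP",
    "ObservableJ",
    "NoePrediction",
    "karplus_j",
    "karplus_extrema",
    "ensemble_j",
    "noe_detectable",
    "relative_noe",
    "predict_noe",
    "coupling_map",
    "noe_pairs",
    "NOE_THRESHOLD",
    "REFERENCE_PAIR",
]

#: Strict detectability cutoff for an inter-proton NOE, in angstroms.
NOE_THRESHOLD = 4.5
#: Intra-residue reference proton pair for relative NOE intensities.
REFERENCE_PAIR = ("H1'", "H2'")


@dataclass(frozen=True)
class KarplusCoefficients:
    """Coefficients of ``J(phi) = A cos^2 phi + B cos phi + C`` in Hz."""

    A: float
    B: float
    C: float
    tag: str = "custom"


CCOP = KarplusCoefficients(6.9, -3.4, 0.7, tag="CCOP")
HCOP = KarplusCoefficients(15.3, -6.1, 1.6, tag="HCOP")


def karplus_j(phi_deg, k: KarplusCoefficients):
    """Evaluate the Karplus curve at torsion ``phi_deg`` (degrees)."""
    c = np.cos(np.radians(np.asarray(phi_deg, float)))
    j = k.A * c * c + k.B * c + k.C
    if j.ndim == 0:
        return float(j)
    return j


def karplus_extrema(k: KarplusCoefficients) -> tuple[float, float]:
    """Global (min, max) of the Karplus curve over all torsions.

    Closed form: candidates are cos phi = +/-1 plus the interior
    stationary point cos phi = -B / (2A) when it lies in [-1, 1].
    """
    cands = [1.0, -1.0]
    if k.A != 0:
        c_star = -k.B / (2.0 * k.A)
        if -1.0 <= c_star <= 1.0:
            cands.append(c_star)
    vals = [k.A * c * c + k.B * c + k.C for c in cands]
    return min(vals), max(vals)


@dataclass(frozen=True)
class ObservableJ:
    """An ensemble-averaged three-bond coupling."""

    pair: str  # e.g. "P-C2'"
    torsion_label: str
    coefficients: KarplusCoefficients
    j_mean: float
    per_frame: np.ndarray | None = None

    def __post_init__(self):
        lo, hi = karplus_extrema(self.coefficients)
        if not (lo - 1e-9 <= self.j_mean <= hi + 1e-9):
            raise ValueError(
                f"averaged J {self.j_mean:.3f} Hz outside the attainable range "
                f"[{lo:.3f}, {hi:.3f}] of the {self.coefficients.tag} curve"
            )


def ensemble_j(
    angles, k: KarplusCoefficients, *, pair: str = "", torsion_label: str = "",
    keep_per_frame: bool = False,
) -> ObservableJ:
    """Frame-wise Karplus evaluation followed by arithmetic averaging.

    ``angles`` is a per-frame torsion array (degrees) or a
    :class:`TorsionSummary`.
    """
    if isinstance(angles, TorsionSummary):
        torsion_label = torsion_label or angles.label
        angles = angles.angles
    a = np.asarray(angles, float)
    if a.size == 0:
        raise ValueError("cannot average a coupling over zero frames")
    j = karplus_j(a, k)
    return ObservableJ(
        pair=pair,
        torsion_label=torsion_label,
        coefficients=k,
        j_mean=float(np.mean(j)),
        per_frame=np.asarray(j) if keep_per_frame else None,
    )


def noe_detectable(d: "DistanceSummary | float", threshold: float = NOE_THRESHOLD) -> bool:
    """Strict distance criterion: NOE measurable iff d < threshold.

    For a :class:`DistanceSummary` the governing distance is the
    r^-6-effective one (the physically NOE-relevant average).
    """
    governing = d.effective_distance if isinstance(d, DistanceSummary) else float(d)
    return governing < threshold


def relative_noe(d: float, d_ref: float) -> float:
    """NOE of a pair at distance ``d`` relative to a reference pair.

    Reciprocal-sixth-power scaling: ``(d_ref / d)^6``; strictly
    decreasing in ``d``.
    """
    if not (d > 0 and d_ref > 0):
        raise ValueError("distances must be positive")
    return (d_ref / d) ** 6


@dataclass(frozen=True)
class NoePrediction:
    """Detectability verdict and relative intensity for one proton pair."""

    pair: tuple[str, str]
    effective_distance: float
    mean_distance: float
    detectable: bool
    detectable_by_mean: bool
    relative_intensity: float
    threshold: float = NOE_THRESHOLD

    def __post_init__(self):
        if self.relative_intensity <= 0:
            raise ValueError("relative NOE intensity must be positive")


def predict_noe(
    summary: DistanceSummary,
    reference: "DistanceSummary | float",
    threshold: float = NOE_THRESHOLD,
) -> NoePrediction:
    """Full NOE prediction for one pair against a reference pair."""
    d_ref = (
        reference.effective_distance
        if isinstance(reference, DistanceSummary)
        else float(reference)
    )
    return NoePrediction(
        pair=summary.pair,
        effective_distance=summary.effective_distance,
        mean_distance=summary.mean_distance,
        detectable=noe_detectable(summary, threshold),
        detectable_by_mean=summary.mean_distance < threshold,
        relative_intensity=relative_noe(summary.effective_distance, d_ref),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Observable maps for the three compounds
# ---------------------------------------------------------------------------

# P-Cx couplings go through the C-C-O-P torsion of the coupled carbon,
# P-Hx couplings through H-C-O-P.
_COUPLING_MAP: dict[int, list[tuple[str, KarplusCoefficients, tuple[str, str, str, str]]]] = {
    1: [  # 1->3 linkage: phosphate on O3
        ("P-C2", CCOP, ("C2", "C3", "O3", "P")),
        ("P-C4", CCOP, ("C4", "C3", "O3", "P")),
        ("P-C2'", CCOP, ("C2'", "C1'", "O1'", "P")),
        ("P-H1'", HCOP, ("H1'", "C1'", "O1'", "P")),
        ("P-H3", HCOP, ("H3", "C3", "O3", "P")),
    ],
    2: [  # 1->4 linkage: phosphate on O4
        ("P-C3", CCOP, ("C3", "C4", "O4", "P")),
        ("P-C5", CCOP, ("C5", "C4", "O4", "P")),
        ("P-C2'", CCOP, ("C2'", "C1'", "O1'", "P")),
        ("P-H1'", HCOP, ("H1'", "C1'", "O1'", "P")),
        ("P-H4", HCOP, ("H4", "C4", "O4", "P")),
    ],
    3: [  # 1->6 linkage: phosphate on O6
        ("P-C5", CCOP, ("C5", "C6", "O6", "P")),
        ("P-C2'", CCOP, ("C2'", "C1'", "O1'", "P")),
        ("P-H1'", HCOP, ("H1'", "C1'", "O1'", "P")),
        ("P-H6a", HCOP, ("H6a", "C6", "O6", "P")),
        ("P-H6b", HCOP, ("H6b", "C6", "O6", "P")),
    ],
}

_NOE_PAIRS: dict[int, list[tuple[str, str]]] = {
    1: [("H1'", "H3"), ("H1'", "H2")],
    2: [("H1'", "H4"), ("H1'", "H6a"), ("H1'", "H6b")],
    3: [("H1'", "H6a"), ("H1'", "H6b")],
}


def coupling_map(compound: int) -> list[tuple[str, KarplusCoefficients, TorsionDefinition]]:
    """Coupled pairs, Karplus sets and torsion definitions for a compound."""
    if compound not in _COUPLING_MAP:
        raise ValueError(f"unknown compound {compound!r}; valid: [1, 2, 3]")
    return [
        (pair, k, TorsionDefinition(atoms, label=pair))
        for pair, k, atoms in _COUPLING_MAP[compound]
    ]


def noe_pairs(compound: int) -> list[tuple[str, str]]:
    """Inter-residue proton pairs with tabulated distances for a compound."""
    if compound not in _NOE_PAIRS:
        raise ValueError(f"unknown compound {compound!r}; valid: [1, 2, 3]")
    return list(_NOE_PAIRS[compound])
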