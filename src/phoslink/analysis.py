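"""Ensemble reduction: distance and torsion statistics.

Two distance averages are always reported for a proton pair: the plain
arithmetic mean over frames and the r^-6-weighted effective distance
``<r^-6>^(-1/6)``.  The effective distance is the one that governs NOE
intensity; by the power-mean inequality it never exceeds the arithmetic
mean, and close-approach frames dominate it.

Torsion statistics use circular (vector) means -- a naive average is
wrong for angles near the +/-180 wrap -- plus rotamer-well occupancies
from the g+/g-/t classification windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geom
from .ensemble import Ensemble, TorsionTrajectory
from .rotamers import CANONICAL_STATES, RotamerState, classify_rotamer

__all__ = [
    "DistanceSummary",
    "TorsionSummary",
    "summarize_distance",
    "summarize_torsion",
    "detect_transitions",
    "effective_distance",
    "circular_mean",
]


def effective_distance(distances) -> float:
    """The NOE-relevant r^-6 average: ``<r^-6>^(-1/6)``."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValueError("cannot average an empty distance set")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def circular_mean(angles_deg) -> float:
    """Circular mean of angles in degrees, result in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, float))
    if a.size == 0:
        raise ValueError("cannot average an empty angle set")
    return geom.normalize_angle(
        float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))
    )


@dataclass(frozen=True)
class DistanceSummary:
    """Frame-averaged statistics for one atom pair."""

    pair: tuple[str, str]
    mean_distance: float
    effective_distance: float
    n_frames: int
    min_distance: float
    max_distance: float

    def __post_init__(self):
        if not (0 < self.effective_distance <= self.mean_distance + 1e-12):
            raise ValueError(
                "effective distance must be positive and cannot exceed the mean "
                f"({self.effective_distance} vs {self.mean_distance})"
            )


@dataclass(frozen=True)
class TorsionSummary:
    """Circular mean and rotamer occupancy of one torsion over frames."""

    label: str
    angles: np.ndarray
    mean: float
    occupancy: dict[RotamerState, float]

    @property
    def occupancy_triple(self) -> tuple[float, float, float]:
        """(g+, g-, t) occupancies in canonical state order."""
        return tuple(self.occupancy[s] for s in CANONICAL_STATES)


def summarize_distance(ensemble: Ensemble, a: str, b: str) -> DistanceSummary:
    """Arithmetic-mean and r^-6-effective distance for one atom pair."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot summarise an empty ensemble")
    d = ensemble.distances(a, b)
    return DistanceSummary(
        pair=(a, b),
        mean_distance=float(d.mean()),
        effective_distance=effective_distance(d),
        n_frames=ensemble.n_frames,
        min_distance=float(d.min()),
        max_distance=float(d.max()),
    )


def _angles_for(source, label):
    if isinstance(source, TorsionTrajectory):
        return source.column(label)
    if isinstance(source, Ensemble):
        return source.torsions(label)
    raise TypeError("source must be a TorsionTrajectory or an Ensemble")


def summarize_torsion(source, label: str) -> TorsionSummary:
    """Circular mean and g+/g-/t occupancies for a labelled torsion.

    ``source`` may be a :class:`TorsionTrajectory` (angles read off the
    stored columns) or an :class:`Ensemble` (angles measured from the
    coordinates frame by frame).
    """
    angles = geom.normalize_angle(np.asarray(_angles_for(source, label), float))
    states = [classify_rotamer(a) for a in angles]
    n = len(states)
    occ = {s: sum(1 for st in states if st is s) / n for s in CANONICAL_STATES}
    return TorsionSummary(label=label, angles=angles, mean=circular_mean(angles), occupancy=occ)


def detect_transitions(
    traj: "TorsionTrajectory | np.ndarray", label: str | None = None
) -> list[tuple[int, RotamerState, RotamerState]]:
    """Rotamer-state change points along a trajectory.

    Returns one ``(frame, from_state, to_state)`` event per consecutive
    pair of frames whose classifications differ; ``frame`` is the
    1-based index of the first frame in the new state.
    """
    if isinstance(traj, TorsionTrajectory):
        if label is None:
            raise ValueError("a torsion label is required with a TorsionTrajectory")
        angles = traj.column(label)
    else:
        angles = np.asarray(traj, float)
    if angles.shape[0] < 2:
        raise ValueError("transition detection needs at least two frames")
    states = [classify_rotamer(a) for a in angles]
    events = []
    for i in range(1, len(states)):
        if states[i] is not states[i - 1]:
            events.append((i + 1, states[i - 1], states[i]))
    return events
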