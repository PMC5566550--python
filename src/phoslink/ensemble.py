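"""Synthetic conformational ensembles standing in for MD trajectories.

The reference simulations these ensembles emulate are 50-ns molecular
dynamics runs with snapshots every 2 ps (25000 frames).  Here each frame
is drawn independently: every free torsion picks a staggered well
(gauche+/gauche-/trans) from a per-torsion population triple and adds
von Mises angular noise around the well center.  A counter-ion flag
switches the anomeric O5'-C1'-O1'-P torsion between a gauche-dominant
population (counter-ion present, exo-anomeric effect operative) and a
trans-dominant one (bare phosphate anion, reverse exo-anomeric effect).

Because frames are independent, the ensembles reproduce well
*populations* and ensemble-averaged observables, not kinetics; torsion
traces only qualitatively resemble real MD time series.

An optional steric filter (used by the pipeline) rejects frames whose
independently drawn torsions produce severe non-bonded overlap --
conformations a real force field would never visit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .builder import (
    Structure,
    TorsionDefinition,
    assemble_disaccharide_frames,
    disaccharide_torsion_definitions,
    free_torsion_labels,
)
from .rotamers import ConformerSpec, Linkage, RotamerState, classify_rotamer, CANONICAL_STATES

__all__ = [
    "SamplerConfig",
    "TorsionTrajectory",
    "Ensemble",
    "n_snapshots",
    "default_populations",
    "default_sampler_config",
    "sample_torsions",
    "realize_ensemble",
    "sample_ensemble",
    "clash_mask",
    "DEFAULT_N_FRAMES",
    "DEFAULT_FRAME_SPACING_PS",
    "DEFAULT_SPREAD_DEG",
    "DEFAULT_CLASH_FRACTION",
]

DEFAULT_N_FRAMES = 25000
DEFAULT_FRAME_SPACING_PS = 2.0
DEFAULT_SPREAD_DEG = 15.0
#: A frame counts as sterically impossible when any atom pair at
#: bond-graph distance >= 4 comes closer than this fraction of the sum
#: of the two van der Waals radii.  For a Lennard-Jones pair, 80% of the
#: contact distance corresponds to roughly 1 kT of repulsion at room
#: temperature -- the edge of what a thermal ensemble visits -- whereas
#: substantially smaller separations are many kT uphill.
DEFAULT_CLASH_FRACTION = 0.8

_VDW_RADII = {"H": 1.10, "C": 1.70, "O": 1.52, "P": 1.80}

_WELL_CENTERS = np.array([60.0, -60.0, 180.0])  # g+, g-, t


def n_snapshots(length_ns: float, spacing_ps: float) -> int:
    """Number of snapshots written for a trajectory of ``length_ns``.

    ``floor(length * 1000 / spacing)``; 50 ns at 2-ps spacing gives the
    canonical 25000 structures.
    """
    if not (length_ns > 0 and spacing_ps > 0):
        raise ValueError("trajectory length and snapshot spacing must be positive")
    return int(math.floor(length_ns * 1000.0 / spacing_ps))


def default_populations(
    linkage: "Linkage | str | int", counterion_present: bool
) -> dict[str, tuple[float, float, float]]:
    """Default per-torsion well populations (g+, g-, t).

    The linker torsions and the reducing-end rotamer are unbiased (no
    population data exist for them); the anomeric torsion encodes the
    counter-ion effect: gauche-dominant with the charge shielded,
    trans-dominant without.  The 1->6 hydroxymethyl omega torsion gets
    the usual gg/gt-dominant pyranose weighting.
    """
    linkage = Linkage.coerce(linkage)
    third = 1.0 / 3.0
    pops = {
        "anomeric": (0.9, 0.0, 0.1) if counterion_present else (0.1, 0.0, 0.9),
        "zeta1": (third, third, third),
        "zeta2": (third, third, third),
        "reducing_end": (third, third, third),
    }
    if linkage is Linkage.ONE_SIX:
        # omega = O5-C5-C6-O6: gg (-60) and gt (+60) dominate, tg minor
        pops["omega"] = (0.4, 0.5, 0.1)
    return pops


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration of the torsion-well sampler.

    ``populations`` maps torsion labels to (g+, g-, t) probability
    triples; ``spread`` is the per-well circular standard deviation in
    degrees; ``restrained_torsions`` maps labels to ``(center, hold)``
    pairs -- with ``hold=True`` the torsion is confined to the well
    containing ``center`` (the MD analogue is a torsional restraint).
    """

    populations: Mapping[str, tuple[float, float, float]]
    n_frames: int = DEFAULT_N_FRAMES
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS
    spread: float = DEFAULT_SPREAD_DEG
    seed: int = 0
    counterion_present: bool = True
    restrained_torsions: Mapping[str, tuple[float, bool]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.spread > 0:
            raise ValueError("angular spread must be positive")
        for label, p in self.populations.items():
            p = tuple(p)
            if len(p) != 3 or any(x < 0 for x in p):
                raise ValueError(f"population triple for {label!r} must be 3 non-negatives")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(
                    f"populations for {label!r} sum to {sum(p)!r}, expected 1"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.populations)


def default_sampler_config(
    linkage: "Linkage | str | int",
    *,
    seed: int,
    counterion_present: bool = True,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS,
    spread: float = DEFAULT_SPREAD_DEG,
    hold_anomeric: bool = False,
    population_overrides: Mapping[str, tuple[float, float, float]] | None = None,
) -> SamplerConfig:
    """The standard sampler configuration for one dimannoside.

    ``hold_anomeric=True`` emulates the torsional restraint used in the
    production simulations, pinning O5'-C1'-O1'-P inside the gauche+
    well.
    """
    pops = default_populations(linkage, counterion_present)
    if population_overrides:
        for k, v in population_overrides.items():
            if k not in pops:
                raise ValueError(f"unknown torsion label {k!r} for linkage {linkage!r}")
            pops[k] = tuple(v)
    restrained = {"anomeric": (60.0, True)} if hold_anomeric else {}
    return SamplerConfig(
        populations=pops,
        n_frames=n_frames,
        frame_spacing=frame_spacing,
        spread=spread,
        seed=seed,
        counterion_present=counterion_present,
        restrained_torsions=restrained,
    )


@dataclass
class TorsionTrajectory:
    """Per-frame torsion angles (degrees) for a set of labelled torsions."""

    labels: tuple[str, ...]
    angles: np.ndarray  # (n_frames, n_labels), in (-180, 180]
    frame_spacing: float
    config: SamplerConfig | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        if self.angles.ndim != 2 or self.angles.shape[1] != len(self.labels):
            raise ValueError("angles must have shape (n_frames, n_labels)")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown torsion label {label!r}; available: {list(self.labels)}"
            ) from None
        return self.angles[:, i]

    def states(self, label: str) -> list[RotamerState]:
        return [classify_rotamer(a) for a in self.column(label)]

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("frame,time_ps," + ",".join(self.labels) + "\n")
        for i, row in enumerate(self.angles):
            t = i * self.frame_spacing
            buf.write(f"{i + 1},{t:g}," + ",".join(f"{a:.6f}" for a in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, frame_spacing: float | None = None) -> "TorsionTrajectory":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split(",")
        labels = tuple(header[2:])
        rows = [ln.split(",") for ln in lines[1:]]
        angles = np.array([[float(x) for x in r[2:]] for r in rows])
        if frame_spacing is None:
            times = [float(r[1]) for r in rows]
            frame_spacing = times[1] - times[0] if len(times) > 1 else DEFAULT_FRAME_SPACING_PS
        return cls(labels, angles, frame_spacing)


def _vonmises_kappa(spread_deg: float) -> float:
    sigma = math.radians(spread_deg)
    return 1.0 / (sigma * sigma)


def _draw_torsion(rng, n, populations, spread, restraint=None) -> np.ndarray:
    """Draw n angles for one torsion; honours a hold restraint."""
    from .geometry import normalize_angle

    kappa = _vonmises_kappa(spread)
    if restraint is not None and restraint[1]:
        center, _ = restraint
        well = classify_rotamer(center)
        draws = normalize_angle(center + np.degrees(rng.vonmises(0.0, kappa, size=n)))
        # confine to the well's classification window (truncated draw)
        bad = np.array([classify_rotamer(a) is not well for a in np.atleast_1d(draws)])
        while bad.any():
            redraw = normalize_angle(
                center + np.degrees(rng.vonmises(0.0, kappa, size=int(bad.sum())))
            )
            draws[bad] = redraw
            bad = np.array([classify_rotamer(a) is not well for a in np.atleast_1d(draws)])
        return draws
    wells = rng.choice(3, size=n, p=np.asarray(populations, float))
    centers = _WELL_CENTERS[wells]
    noise = np.degrees(rng.vonmises(0.0, kappa, size=n))
    return normalize_angle(centers + noise)


def sample_torsions(config: SamplerConfig, rng=None) -> TorsionTrajectory:
    """Draw a torsion-state trajectory from the sampler configuration.

    Frames are independent draws; identical seed and configuration give
    bit-identical trajectories.  An explicit ``rng`` may be supplied for
    chunked sampling (the seed in ``config`` is then ignored).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cols = []
    for label in config.labels:
        restraint = config.restrained_torsions.get(label)
        cols.append(
            _draw_torsion(rng, config.n_frames, config.populations[label], config.spread, restraint)
        )
    angles = np.column_stack(cols)
    return TorsionTrajectory(config.labels, angles, config.frame_spacing, config=config)


class Ensemble:
    """An ordered stack of structures sharing one atom roster.

    ``topology`` is a :class:`Structure` (frame 0 coordinates);
    ``coords`` has shape (n_frames, n_atoms, 3).
    """

    def __init__(
        self,
        topology: Structure,
        coords: np.ndarray,
        frame_spacing: float = DEFAULT_FRAME_SPACING_PS,
        torsion_definitions: Mapping[str, TorsionDefinition] | None = None,
    ):
        self.topology = topology
        self.coords = np.asarray(coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(topology):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        self.frame_spacing = frame_spacing
        self.torsion_definitions = dict(torsion_definitions or {})

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Structure:
        t = self.topology
        return Structure(t.names, t.elements, t.residues, self.coords[i], t.bonds, t.provenance)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    def distances(self, a: str, b: str) -> np.ndarray:
        """Per-frame distance between two named atoms."""
        ia, ib = self.topology.index(a), self.topology.index(b)
        return np.linalg.norm(self.coords[:, ia] - self.coords[:, ib], axis=-1)

    def torsions(self, torsion: "TorsionDefinition | str | Sequence[str]") -> np.ndarray:
        """Per-frame dihedral for a torsion definition or known label."""
        from . import geometry as geom

        if isinstance(torsion, str):
            try:
                torsion = self.torsion_definitions[torsion]
            except KeyError:
                raise KeyError(
                    f"unknown torsion label {torsion!r}; known: {sorted(self.torsion_definitions)}"
                ) from None
        names = torsion.atoms if isinstance(torsion, TorsionDefinition) else tuple(torsion)
        idx = [self.topology.index(n) for n in names]
        p = [self.coords[:, i] for i in idx]
        return geom.dihedral(*p)

    def subset(self, mask_or_indices) -> "Ensemble":
        return Ensemble(
            self.topology,
            self.coords[mask_or_indices],
            self.frame_spacing,
            self.torsion_definitions,
        )


def realize_ensemble(spec: ConformerSpec, traj: TorsionTrajectory) -> Ensemble:
    """Build one structure per trajectory frame (frame count preserved).

    The trajectory must provide every free torsion of the spec's linkage;
    missing labels raise ``KeyError``.
    """
    labels = free_torsion_labels(spec.linkage)
    missing = [l for l in labels if l not in traj.labels]
    if missing:
        raise KeyError(f"trajectory lacks torsion labels {missing} required by {spec.linkage.value}")
    torsions = {l: traj.column(l) for l in labels}
    topology, coords = assemble_disaccharide_frames(spec.linkage, torsions, provenance=spec)
    return Ensemble(
        topology,
        coords,
        frame_spacing=traj.frame_spacing,
        torsion_definitions=disaccharide_torsion_definitions(spec.linkage),
    )


def _clash_pairs(topology: Structure, min_graph_separation: int = 4):
    """Atom index pairs at bond-graph distance >= the separation.

    Returns ``(pairs, contact)`` where ``contact[i]`` is the van der
    Waals contact distance (sum of radii) of pair ``i``.
    """
    n = len(topology)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in topology.bonds:
        adj[a].append(b)
        adj[b].append(a)
    pairs = []
    contact = []
    radii = [_VDW_RADII.get(e, 1.7) for e in topology.elements]
    for src in range(n):
        # BFS out to the separation horizon
        dist = {src: 0}
        frontier = [src]
        for _ in range(1, min_graph_separation):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = 1
                        nxt.append(v)
            frontier = nxt
        for tgt in range(src + 1, n):
            if tgt not in dist:
                pairs.append((src, tgt))
                contact.append(radii[src] + radii[tgt])
    return np.asarray(pairs, dtype=int), np.asarray(contact, dtype=float)


def clash_mask(
    ensemble: Ensemble, fraction: float = DEFAULT_CLASH_FRACTION, _pairs=None
) -> np.ndarray:
    """Boolean mask of frames containing a severe steric overlap.

    A frame clashes when any atom pair at bond-graph distance >= 4 comes
    closer than ``fraction`` times its van der Waals contact distance.
    """
    pairs, contact = _pairs if _pairs is not None else _clash_pairs(ensemble.topology)
    if len(pairs) == 0:
        return np.zeros(ensemble.n_frames, dtype=bool)
    diff = ensemble.coords[:, pairs[:, 0]] - ensemble.coords[:, pairs[:, 1]]
    d2 = np.einsum("fpk,fpk->fp", diff, diff)
    limit = (fraction * contact) ** 2
    return (d2 < limit[None, :]).any(axis=1)


def sample_ensemble(
    spec: ConformerSpec,
    config: SamplerConfig,
    *,
    reject_clashes: bool = True,
    clash_fraction: float = DEFAULT_CLASH_FRACTION,
    max_tries: int = 200,
) -> tuple[TorsionTrajectory, Ensemble]:
    """Sample torsions and realise an ensemble of exactly ``n_frames``.

    With ``reject_clashes`` the sampler discards sterically impossible
    frames and keeps drawing (one seeded generator, so the result is
    deterministic) until the requested frame count is reached.
    """
    rng = np.random.default_rng(config.seed)
    if not reject_clashes:
        traj = sample_torsions(config, rng=rng)
        return traj, realize_ensemble(spec, traj)

    kept_angles = []
    kept_coords = []
    kept = 0
    topology = None
    pair_cache = None
    tdefs = disaccharide_torsion_definitions(spec.linkage)
    for _ in range(max_tries):
        traj = sample_torsions(config, rng=rng)
        ens = realize_ensemble(spec, traj)
        topology = ens.topology
        if pair_cache is None:
            pair_cache = _clash_pairs(topology)
        ok = ~clash_mask(ens, fraction=clash_fraction, _pairs=pair_cache)
        kept_angles.append(traj.angles[ok])
        kept_coords.append(ens.coords[ok])
        kept += int(ok.sum())
        if kept >= config.n_frames:
            break
    else:
        raise RuntimeError(
            f"could not collect {config.n_frames} clash-free frames in {max_tries} rounds; "
            "the configuration may be sterically infeasible"
        )
    angles = np.concatenate(kept_angles)[: config.n_frames]
    coords = np.concatenate(kept_coords)[: config.n_frames]
    traj = TorsionTrajectory(config.labels, angles, config.frame_spacing, config=config)
    ensemble = Ensemble(topology, coords, config.frame_spacing, tdefs)
    return traj, ensemble
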