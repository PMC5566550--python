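# Methods

## Model overview

The package treats a phosphodiester-linked dimannoside as a small set of
rotatable bonds decorating rigid idealised sugar residues. The
conformational state is the vector of free torsions

| label | torsion | present in |
|---|---|---|
| `anomeric` | O5′-C1′-O1′-P | all |
| `zeta1` | C1′-O1′-P-Ox | all |
| `zeta2` | Cx-Ox-P-O1′ | all |
| `reducing_end` | P-Ox-Cx-Hx | all (x = 3, 4; Hx = H6a for x = 6) |
| `omega` | O5-C5-C6-O6 | 1→6 only |

All angles are in degrees, signed dihedrals in (−180, 180] under the
IUPAC convention (two-plane atan2 formulation; the worked anchor case
A(0,0,0) B(1,0,0) C(1,1,0) D(1,1,1) gives +90°). Staggered wells are
classified into g⁺ = (0°, 120°), g⁻ = (−120°, 0°], t = the remainder;
the explicit boundary rules (120° → t, 0° → g⁻) make the classifier
total and testable. Canonical state order g⁺ < g⁻ < t fixes enumeration
order and the canonical form of exchange-symmetric pairs.

The mixed-gauche exclusion removes {g⁺, g⁻} as an *unordered* pair: a
diester in that state collapses to a trans conformer during optimisation
(oxygen–oxygen repulsion), and the repulsion argument is
order-independent. This yields 9 − 2 = 7 linker conformers for
inequivalent arms and 6 − 1 = 5 for symmetric dimethyl phosphate.

## Structure building

Residues and the linker are placed by natural-extension-reference-frame
(NeRF) chaining from internal coordinates. Template values: C-C 1.52 Å,
C-O 1.43 Å, C-H 1.09 Å, O-H 0.96 Å, P-O(ester) 1.60 Å, P-O(anionic)
1.48 Å, tetrahedral angles 109.47°, ester C-O-P angles 120°. The ⁴C₁
pyranose ring uses ring angles of 110.5° with alternating torsions of
±57.4°, the magnitude consistent with closure at that angle; closure is
checked (C1-O5 comes out 1.55 Å, 8.7 % above the C-O template, within
the 10 % tolerance), not minimised — determinism is preferred over
geometric polish. Ring substituents are placed by tetrahedral
completion and assigned axial/equatorial per the α-D-manno pattern
(O1, O2 axial; O3, O4, C6 equatorial). The enantiomer convention was
validated against an independently embedded conformer of methyl
α-D-mannopyranoside (ETKDG + MMFF): ring torsion signs, the
H1-C1-C2-H2 torsion (−65° vs −68°), the exo-anomeric preference
(+60° well vs +71°) and the H1-H2 distance (2.50 vs 2.55 Å) all agree.

The reducing residue is attached by exact rigid-body mapping: the
bridging Ox, Cx and Hx anchor positions are NeRF-placed from ζ₂ and the
rotamer torsion, and the rest of the (rigid) residue is superposed by a
three-point frame. For the 1→6 linkage the residue splits into an
exocyclic arm block and a ring block joined at C5-C6, so ω remains an
independent degree of freedom. Assembly is vectorised over frames: a
25000-frame ensemble of 52-atom structures builds in about a second.

Exocyclic hydroxyl protons sit at staggered default torsions; they
enter no reported observable.

## The synthetic ensemble generator

The generator emulates 50-ns MD runs written every 2 ps (25000 frames
by the floor rule; both are defaults). Every frame draws each free
torsion independently: a well from the torsion's (g⁺, g⁻, t)
population triple, then von Mises noise with circular spread σ = 15°
(κ = 1/σ²) about the well center. One seeded NumPy generator drives a
whole run, so identical seed + configuration is bit-identical.

Default populations:

* `anomeric`: (0.9, 0, 0.1) with a counter-ion, (0.1, 0, 0.9) without.
  This encodes the qualitative finding that shielding the phosphate
  charge restores the exo-anomeric gauche preference, while the bare
  anion flips the torsion to trans (reverse exo-anomeric effect). The
  magnitudes are free parameters, not fitted values. A `hold` restraint
  can instead confine the torsion to its well (truncated draw),
  emulating the torsional restraint used in production MD.
* `zeta1`, `zeta2`, `reducing_end`: uniform (⅓, ⅓, ⅓) — no population
  data exist for them, and uniformity adds no information.
* `omega` (1→6): (0.4, 0.5, 0.1) for (g⁺, g⁻, t) = (gt, gg, tg), the
  usual hydroxymethyl weighting of gluco/manno pyranoses.

**Steric filter.** Independent draws produce conformations a force
field would never visit. The pipeline therefore rejects frames in which
any atom pair at bond-graph distance ≥ 4 approaches closer than 80 % of
the sum of its van der Waals radii (H 1.10, C 1.70, O 1.52, P 1.80 Å).
The 0.8 fraction comes from a Lennard-Jones estimate: at 80 % of the
contact distance the repulsion is roughly 1 kT at room temperature —
the edge of thermal accessibility — while smaller separations are many
kT uphill. Rejected frames are replaced by further draws from the same
generator until the requested frame count is reached, so frame counts
are exact and runs deterministic. Rejection rates under uniform linker
populations are substantial (≈80 % for the 1→3 and 1→6 compounds, ≈98 %
for the sterically crowded 1→4 compound), which is itself a statement
about how little of the independent-torsion space is physically
accessible.

**What the generator does not emulate.** Frames are independent: there
are no kinetics, no temporal correlation, and — crucially — no
energetic correlations *between* torsions beyond hard-sphere exclusion.
Ensemble averages over well populations are meaningful; transition
traces are only qualitative. Passing tests therefore validate the
observable machinery (geometry, averaging, Karplus evaluation) and the
encoded population logic, not force-field realism.

A documented consequence: the generator cannot reproduce the spatial
separation of the two residues in the 1→6 compound. The H6a/b protons
sit on the carbon bonded directly to the bridging O6, so the torsion
path H1′-C1′-O1′-P-O6-C6-H6 has exactly the same length and
ideal-geometry statistics as the H1′-…-O3-C3-H3 path of the 1→3
compound. Under independent well sampling the two distance
distributions are necessarily similar, and the r⁻⁶-effective H1′-H6
distances come out near 3.1–3.2 Å rather than above the 4.5 Å
detectability cutoff (the published MD averages are 4.8/4.7 Å). The
corresponding acceptance test is left failing deliberately: the
separation is produced by force-field torsional correlations that an
independent-well generator cannot represent, and weakening the test
would hide that limitation. The 1→3 and 1→4 compounds, whose NOE
pattern is driven by geometry and exclusion alone, are reproduced
(H1′-H3 effective 3.5 Å vs 3.5 Å reported; H1′-H6a of the 1→4 compound
3.5 Å vs 3.6 Å).

## Observables

* **Couplings.** ³J = A cos²φ + B cos φ + C with (6.9, −3.4, 0.7) for
  C-C-O-P and (15.3, −6.1, 1.6) for H-C-O-P, evaluated per frame and
  arithmetically averaged. The curve is strongly non-linear, so ⟨J(φ)⟩
  ≠ J(⟨φ⟩); the implementation always averages J. Curve ranges
  ([0.281, 11.0] and [0.992, 23.0] Hz) are computed in closed form and
  cross-checked against a dense grid. The H-C-O-P parameterisation was
  derived for nucleotides and is known to overestimate sugar-phosphate
  couplings by more than 1 Hz; it is applied as-is, without correction.
* **Distances.** Both the arithmetic mean and ⟨r⁻⁶⟩^(−1/6) are always
  reported, because published "averaged distances" tables do not state
  which average they contain while NOE physics requires the r⁻⁶ form.
  The effective distance never exceeds the mean (power-mean
  inequality, enforced as an invariant).
* **NOE.** Detectable iff the governing distance is strictly below
  4.5 Å; the r⁻⁶-effective distance governs, with the mean-distance
  verdict also reported. The cutoff is overridable (a 4.0 Å convention
  also circulates). Relative intensity vs the H1′-H2′ reference is
  (d_ref/d)⁶.
* **Torsion statistics.** Circular (vector) means — naive averages are
  wrong near ±180° — plus well occupancies from the classifier.
  Transition detection reports the 1-based index of the first frame in
  each new state.

## Numerical choices and degenerate inputs

Angles normalise via 180 − mod(180 − a, 360), mapping both ±180 to
+180. Dihedrals raise on collinear triples rather than returning a
conventional value. NeRF placement and dihedral measurement share one
sign convention and round-trip to < 10⁻⁴° (tested property). The
truncated draw for held torsions resamples rather than clips, keeping
the within-well distribution shape. Empty ensembles, non-finite angles,
non-positive distances and population triples that do not sum to 1
(tolerance 10⁻⁹) are rejected with explicit errors.

## Problem sizes

Defaults follow the emulated simulations: 25000 frames at 2 ps spacing.
The acceptance-level NOE-pattern checks run all three compounds at the
full default size (about 3.5 minutes end to end, dominated by the 1→4
compound's rejection rate); unit and property tests use 10–10⁴ frames,
where sampler population recovery is already within ±0.02 (> 4 binomial
standard errors at n = 10⁴).

## Known limitations

* Idealised geometry: no force field, no energy minimisation, no
  solvent. Absolute distances can differ from relaxed structures by a
  few tenths of an Å (ring closure error 8.7 % is the largest single
  artefact).
* Independent-frame sampling: no kinetics, no inter-torsion energetics
  (see the 1→6 discussion above); reducing-end coupling predictions
  inherit whatever bias steric rejection induces on the rotamer
  populations.
* Temperature dependence of NOEs is carried as a data fixture only and
  not modelled; chemical shifts (two further fixture tables) are
  metadata only.
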