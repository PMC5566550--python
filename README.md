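# phoslink

Conformational analysis of phosphodiester-linked dimannosides.

Phosphodiester bridges (-O-PO₂⁻-O-) join sugar residues in many natural
polysaccharides — pneumococcal and *Haemophilus* capsular polysaccharides,
yeast phosphomannans — yet the conformational behaviour of the bridge
itself is far less studied than that of ordinary glycosidic bonds.
`phoslink` is a toolkit for reasoning about that bridge in three isomeric
model compounds, the α-D-mannosyl phosphates of methyl α-D-mannoside
linked at O-3 (compound 1), O-4 (compound 2) and O-6 (compound 3). It is
aimed at NMR spectroscopists and modellers who want to connect rotamer
populations of the linker torsions to the observables they can actually
measure: ³¹P three-bond couplings and inter-residue NOEs.

## What it computes

**Rotamer algebra.** Each ester torsion ζ = C-O-P-O occupies a staggered
well g⁺ (+60°), g⁻ (−60°) or t (180°). The package enumerates the 3×3
well combinations, removes the sterically collapsing mixed-gauche pair
{g⁺,g⁻}, reduces by arm-exchange symmetry for symmetric diesters
(dimethyl phosphate: 5 conformers; inequivalent sugar arms: 7), and
expands to the full set of 21 starting conformations per disaccharide
(7 linker conformers × 3 reducing-end P-Ox-Cx-Hx rotamers, anomeric
torsion at its exo-anomeric value of +60°).

**Structure building.** Idealised 3D models (⁴C₁ α-D-mannopyranose
residues, standard bond lengths, tetrahedral angles) are assembled from
internal coordinates by NeRF placement, with every linker torsion —
anomeric O5′-C1′-O1′-P, ζ₁, ζ₂, the reducing-end rotamer, and ω
(O5-C5-C6-O6, 1→6 only) — freely settable and exactly recovered on
measurement.

**Synthetic ensembles.** A seeded torsion-well sampler stands in for the
50 ns / 2 ps-snapshot MD ensembles (25000 frames): each frame draws every
free torsion from a per-torsion well-population triple with von Mises
angular noise, and a steric filter discards frames with severe van der
Waals overlap. A counter-ion flag switches the anomeric torsion between
gauche-dominant (charge shielded, exo-anomeric effect operative) and
trans-dominant (bare anion, reverse exo-anomeric effect).

**Observables.** Per-frame torsions feed Karplus equations

    ³J(C-C-O-P) = 6.9 cos²φ − 3.4 cos φ + 0.7   Hz
    ³J(H-C-O-P) = 15.3 cos²φ − 6.1 cos φ + 1.6  Hz

averaged as ⟨J⟩ over frames (never J of the mean angle). Inter-proton
distances are averaged both arithmetically and as the NOE-relevant
⟨r⁻⁶⟩^(−1/6); an NOE is predicted detectable below 4.5 Å, and relative
intensities scale as (d_ref/d)⁶ against the intra-residue H1′-H2′ pair
(≈2.6 Å). Published experimental tables (distances, relative NOEs,
³J(C,P), ³J(H,P)) ship as fixtures for calculated-vs-experimental
reports.

## Worked example

```bash
phoslink run --compound 1 --seed 7 --n-frames 2000 -o out/
```

prints (abridged):

```
## torsion occupancies
torsion,circular_mean_deg,p_gauche_plus,p_gauche_minus,p_trans
anomeric,68.0153,0.9415,0.0000,0.0585
...

## inter-proton distances (A)
pair,predicted_mean_A,predicted_effective_A,reference_MD_A,dev_mean,dev_effective
H1'-H3,4.7653,3.5078,3.5000,1.2653,0.0078
H1'-H2,4.6054,3.5263,3.3000,1.3054,0.2263

## NOE predictions
pair,effective_A,mean_A,detectable,detectable_by_mean,relative_intensity
H1'-H3,3.5078,4.7653,True,False,0.1324
H1'-H2,3.5263,4.6054,True,False,0.1283
H1'-H2' (reference),2.5044,2.5044,True,True,1.0000

## three-bond couplings (Hz)
pair,predicted,experimental,abs_deviation,published_calculated,published_abs_deviation
P-C2,1.4389,2.7000,1.2611,1.5000,1.2000
P-C4,9.6111,4.4000,5.2111,3.9000,0.5000
P-C2',10.0046,9.2000,0.8046,8.5000,0.7000
P-H1',3.3359,7.6000,4.2641,8.8000,1.2000
P-H3,3.9822,8.0000,4.0178,8.9000,0.9000
```

Reading this: the counter-ion-present ensemble keeps the anomeric torsion
94 % gauche⁺ (exo-anomeric). The r⁻⁶-effective H1′-H3 distance, 3.51 Å,
sits below the 4.5 Å cutoff — the inter-residue NOE observed for the 1→3
compound is predicted — and its intensity relative to H1′-H2′ (0.13)
matches the measured temperature-series value (0.14). The ³J(P-C2′)
coupling through the anomeric torsion is reproduced within 0.8 Hz; the
reducing-end couplings (P-C4, P-H3, P-H1′) deviate by several Hz because
an independent-well torsion sampler only caricatures the true
force-field torsion distributions there (see `docs/methods.md`).

The CLI verbs `enumerate`, `build`, `sample`, `observe`, `run` and
`compare` expose each stage separately; every `run` option can come from
a YAML config file. The same functionality is available as a library
(`phoslink.rotamers`, `.builder`, `.ensemble`, `.analysis`, `.nmr`,
`.pipeline`).

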