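# Methods

## Scope and model

`foldmimic` implements the geometric side of conformational analysis
for peptidomimetic scaffolds: given externally generated conformer
ensembles (Monte Carlo/MM or DFT geometries arrive as SDF/XYZ/PDB; the
package does not sample conformations itself), it decides per
conformer whether the scaffold's anchor atoms reproduce an α-helix,
β-turn or 3₁₀-helix side-chain arrangement, and aggregates the
ensemble into motif percentages. The solid-state modules compute
derived crystallographic quantities and Hirshfeld-surface contact
statistics from their standard published inputs; the Hirshfeld surface
itself (a promolecule electron-density partition) is an upstream
artifact of programs like CrystalExplorer and is consumed, never
generated, here.

## Classification criteria and their tunables

| parameter | default | unit | rationale |
|---|---|---|---|
| helix reference distances | 6.2 / 10.3 / 5.8 | Å | literature i,i+4 / i,i+7 / i+4,i+7 side-chain spacings of an ideal α-helix |
| helix tolerance | ±1.0 | Å | no standard value exists; ±1.0 Å accepts thermal-width deviations while rejecting extended chains (which miss by ≥3 Å). Configurable per run |
| d<sub>α</sub> maximum | 7.0 | Å | the classical β-turn compactness criterion |
| β torsion maximum | 60 | deg | applied to the **absolute value** of the C1–C2–C3–N4 torsion |
| 3₁₀ references | 6.48 / 9.41 / 6.48 | Å | measured once on the ideal 3₁₀ template's Cβ markers (i,i+2 / i,i+4 / i+2,i+4); no printed values exist for this motif |
| H-bond cutoffs | d(H···A) ≤ 2.5, d(D···A) ≤ 3.5, ∠DHA ≥ 120 | Å, deg | standard crystallographic practice |
| energy window | 10 | kcal/mol | conformers above min + window are discarded before summarizing; the boundary is inclusive |

The β-turn flag follows the two-part distance/torsion condition only;
the C10 hydrogen bond is always *evaluated* and reported, and a strict
mode (`require_c10`) folds it into the condition. Ring sizes are
counted over the covalent shortest path from acceptor to donor
hydrogen inclusive, so a classical β-turn H-bond is a 10-ring and a
γ-turn a 7-ring; an α-helix-like fold is signed by both amide N–H
donors closing 7-rings simultaneously. Percentages are rounded
half-up to integers, the convention of printed summary tables, and
need not sum to 100 because motifs can co-occur. The global-minimum
label is "n.d." when the lowest-energy conformer carries no flag or
when conformers tie within 10⁻⁶ kcal/mol with conflicting flags; a
minimum carrying several flags reports the most specific one
(β-turn over α-helix over 3₁₀).

## Ideal templates

Backbones are built by sequential internal-coordinate (NeRF)
placement with fixed bond lengths N–Cα 1.458, Cα–C 1.525, C–N
1.329 Å and angles Cα–C–N 116°, C–N–Cα 121°. The N–Cα–C angle is
tetrahedral (109.5°): with the canonical helix dihedrals
(φ,ψ) = (−57,−47) this yields a 3.6-residues/turn helix with a
1.51 Å rise whose Cβ spacings (6.42, 10.51, 5.55 Å) land on the
literature reference triple; the more common 111° value unwinds the
helix to 3.5 residues/turn and overshoots the i,i+7 spacing by
~0.6 Å, so it was not used. Cβ markers sit at Cα with the improper
torsion C–N–Cα–Cβ = −122.55°, the L-configuration (checked against an
embedded L-alanine). β-turn templates are four residues with
extended termini and the classical Venkatachalam central dihedrals —
I: (−60,−30,−90,0), II: (−60,120,80,0) — the primed types being exact
sign inversions, hence exact mirror images; ω is trans everywhere.
Rebuilt torsions reproduce their inputs to well below 0.5°.

Turn-type fitting uses reflection-free Kabsch superposition
(SVD with determinant sign correction): a mimicry comparison must not
silently invert chirality, which is why the mirrored templates exist
as explicit types. The conformer→template atom mapping is supplied
per compound in the run configuration, because which scaffold atoms
stand in for which backbone atoms is a per-chemistry choice.

## Crystallographic arithmetic

Atomic weights are the IUPAC 2021 standard values and monoisotopic
masses those of the most abundant isotopes; published Mr values
computed from older tables differ by up to a few 0.01 u, which the
±0.05 u comparison tolerance absorbs. F(000) is the neutral-atom
total electron count per cell, Z·Σn<sub>i</sub>Z<sub>i</sub>, with no
anomalous-dispersion terms — that is the integer crystal-data tables
print. Cell volume uses the general triclinic closed form; density is
Z·Mr·1.66054/V. Fractional↔Cartesian conversion delegates to gemmi's
orthogonalization matrices, and symmetry expansion applies each
xyz-triplet operator plus all lattice translations within ±shell
cells without deduplication, tagging every image with its operator
and translation so H-bond records carry their symmetry code.
Geometric H-bond detection excludes acceptors fewer than three
covalent bonds from the donor.

## Hirshfeld contact statistics

Random contacts follow the merged-reciprocal convention
R<sub>XX</sub> = s<sub>X</sub>²·100, R<sub>XY</sub> = 2s<sub>X</sub>s<sub>Y</sub>·100,
so ΣR = (Σs)²·100; enrichments E<sub>XY</sub> = C<sub>XY</sub>/R<sub>XY</sub>
are reported half-up to 1 d.p. and masked when R<sub>XY</sub> < 0.9 %,
below which the ratio of two near-zero percentages is noise. Van der
Waals radii for d_norm are the Bondi set (H 1.20, C 1.70, N 1.55,
O 1.52, Cl 1.75 Å), the CrystalExplorer convention. Fingerprint
histograms use half-open bins (default width 0.01 Å) and by default
size their grid to the data, so counts are always conserved.

## Synthetic generator

The planted ensemble generator is deliberately abstract: a 28-atom
molecule whose anchor groups (helix triad, 3₁₀ triad, turn quartet,
one 10-ring and two 7-ring H-bond chains) are spatially independent,
each drawn from the corresponding ideal template when its motif is
planted and from an extended chain when not, then perturbed by
isotropic Gaussian noise. This makes any label combination
plantable — real ensembles show overlapping motif percentages — and
makes zero-noise recovery exact by construction. What it does *not*
emulate: force-field energetics, correlated intramolecular motion,
steric coupling between the groups, or chemically consistent bond
geometry in the H-bond chains (those bonds are topological, for
ring-size bookkeeping). Passing recovery tests therefore validate the
classifier's logic and noise robustness, not any claim about real
conformer distributions. Energies put the designated global-minimum
conformer at 0 and the rest uniform on (0, 9] kcal/mol so the default
ensemble sits inside the 10 kcal/mol window. All generators are pure
functions of (spec, seed).

The toy crystal inverts the D–H···A triangle (law of cosines, D–H
fixed at 1.0 Å) to place one intramolecular N–H···O bond closing a
10-ring at the requested geometry, plus a second amide donating to
the O of the (x, y−1, z) lattice neighbour; requests whose solution
would put H···A below 1.3 Å or D···A below 2.4 Å are rejected as
clashes. Default test sizes (ensembles of 40–200 conformers, 10 seeds
for the noisy-recovery check, 50 replicates for the turn-ranking
check) keep the full suite under ~10 s.

## Known limitations

- Ensemble motif percentages for real compounds depend on the
  upstream conformer generator and on the helix tolerance; published
  per-compound percentages are engine-dependent and are treated as
  qualitative, not as reproduction targets.
- Published turn-fit RMSDs require the authors' DFT geometries; the
  package checks the fitting machinery's exact internal relations
  (self-fit zero, mirror symmetry, agreement with a quaternion
  oracle) instead.
- No disorder handling, anisotropic displacement parameters, or
  charge bookkeeping in crystal structures; hydrogens are never
  inferred, so structures must arrive with explicit H positions.
- Bond perception for bond-block-free formats is a covalent-radius
  distance criterion (sum + 0.4 Å) reporting single bonds only.
- Surface asphericity and any statistic requiring the actual
  Hirshfeld mesh (shape index, curvedness) are out of scope.
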