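# Methods

## Problem and unit of analysis

Peptide bonds are planar and overwhelmingly *trans* (ω ≈ 180°); *cis*
peptides (ω ≈ 0°) are rare, functionally important, and frequently
mis-modelled because refinement starts from, and is restrained towards,
*trans*.  A peptide modelled in the wrong conformation cannot fully relax:
the X-ray data pull the surrounding atoms towards their true positions
while the restraints hold the wrong isomer, leaving measurable strain.

The unit of analysis is the **tetrapeptide**: four consecutive residues
with complete backbone (+Cβ for non-Gly), the central peptide bond joining
residues 2 and 3 (i−1 and i).  Residue classes are keyed on the residue
*after* the bond: X-Pro, X-Gly and X-Xnpg (anything else), because proline
(no amide H, ring nitrogen) and glycine (no Cβ, high flexibility) behave
differently.

## Selection rules

Entries are used when they are X-ray structures at 3.5 Å or better with at
least one chain of ≥ 25 amino acids.  Windows are kept when every residue
is canonical and complete, all occupancies are 1.0 and all B > 0, no atom
has an alternate location, no residue is a terminus or adjacent to a chain
break (C–N > 2.5 Å or a numbering gap), no Cys is disulfide-bonded
(Sγ–Sγ < 2.5 Å), and no atom outside the window's own chain lies within
2.5 Å of the central carbonyl O.  "Own molecule" is taken as the polymer
chain; covalent adducts are not modelled.  Rejections are logged with the
failed criterion.

## Geometry conventions

Angles are in degrees throughout.  Torsions follow the IUPAC sign
convention and live in (−180°, 180°]; ω for *trans* is reported near ±180°,
never wrapped to 0.  The chiral volume at Cα is the signed triple product
of the N, C, Cβ offsets (≈ +2.5 Å³ for L-residues).  Superposition is
least-squares (Kabsch/SVD) with reflections excluded; degenerate point sets
are rejected rather than silently resolved.

## Conformation states and flip codes

ω classifies as *cis* (|ω| ≤ 30°), *trans* (|ω| ≥ 150°) or **twisted**
(anything between).  Twisted intermediates are real — restraint-dominated
refinement can leave a flipping peptide "halfway" (ω near 80–130°) — and
are never silently binned; comparisons involving them return
"indeterminate".  The cutoffs are configuration-exposed because the
literature reports intermediates but no canonical thresholds.

Pairwise flip assignment superposes model B onto model A on the four Cα
atoms and measures the (C=O, C=O) angle, the (N—H, N—H) angle and the ω
difference.  The amide H is always re-inferred geometrically (1.0 Å from N,
in the C–N–Cα plane, opposite the bisector), since X-ray models rarely
contain it and deposited hydrogens are inconsistent; for proline the N→Cδ
direction is the surrogate, as the ring nitrogen substituent is the closest
analogue for detecting plane inversion.  The carbonyl-flip threshold on the
(C=O, C=O) angle is 90°, the unique symmetric separatrix.  A
same-conformation pair whose N—H flipped but whose C=O did not is
geometrically inconsistent and reported indeterminate.

## Feature set

Per tetrapeptide: Cα–Cα, Cβ–Cβ and O–O distances; φ/ψ of the central
residues, central and flanking ω; the four bond lengths around the central
bond; the bond angles O–C–N, Cα–C–N, Cα–C–O, C–N–Cα, the τ angles
(N–Cα–C) of both central residues and Cα–C–N of the following bond; chiral
volumes at Cα2/Cα3; the C–O–C–O pseudo-torsions (C1–O1–C2–O2 and
C2–O2–C3–O3, virtual torsions over the atoms in that order — the atom
order is a package choice, documented here because the feature name alone
does not fix it); the angle between the central and preceding carbonyls;
the carbonyl-O bump score; the carbonyl–helix alignment; 3-state secondary
structure of all four residues; B factors of C2, O2, N3, Cα2, Cα3; the
resolution; and the WH penalty score.  Gly rows carry NaN for Cβ-dependent
fields; for tree models these are encoded as −1 so absence is branchable.

**Bump score.**  Sum of van der Waals overlaps max(0, r_O + r_a − d) over
atoms within 4.0 Å of the central O, excluding the backbone of the two
central residues.  Fixed radii: O 1.52, N 1.55, C 1.70, S 1.80 Å.  The
score is expressed in Å of overlap; the 0.26 decision threshold of the
X-Pro rule originates from a different scoring implementation and may need
local recalibration — it is configuration-exposed for exactly that reason.

**Secondary structure.**  A minimal internal Kabsch–Sander implementation:
electrostatic H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol with inferred amide H, bond when E < −0.5; H requires two
consecutive i→i+4 turns, E an (anti)parallel bridge pattern, everything
else is C.  A reader for standard DSSP files can override it.  Residues
with incomplete backbone score C with a warning.

**Carbonyl–helix alignment.**  When a helix of ≥ 4 H residues lies within
±8 sequence positions, the angle between the central C=O and the helix
axis (least-squares line through centroids of consecutive 4-Cα windows).
Helical carbonyls align with the axis (< 30°); a flipped plane inside a
helix points against it.

**Weiss–Hilgenfeld penalty (D_tot).**  The published coefficients of the
original penalty function are not available here, so the score is a
documented surrogate with the same zero point and monotonicity: the sum of
squared standardized deviations of the strain variables (φ_i; the angles
O–C–N, Cα–C–N, Cα–C–O, C–N–Cα; the Cα–Cα distance) from the ideal trans
reference geometry, with scales 2° for bond angles, 30° for φ and 0.05 Å
for the distance (typical refined spreads).  It is zero at the reference
build and strictly positive off it, and is defined for X-Xnpg peptides
only.  The decision thresholds 143.10 (original) and 82.256 (redetermined)
are exposed as constants; because the surrogate's scale differs from the
original implementation, quantitative agreement of scores is not claimed —
only the threshold constants and the qualitative behaviour are.  One of
the published strain variables is ambiguous between Cα–C–N(i) and
Cα–C–N(i−1); the N(i) reading is used (the N(i−1) variant is a 1–3
non-bonded angle with little information), and τ2 = N–Cα–C of residue 2
is carried in the feature set so both flavours of angle information are
available to the classifiers.

## Explicit rules

**X-Pro positive-φ tree.**  X-Pro peptides with φ_i > 0 are either genuine
tc− flips or trans prolines with broken nitrogen chirality ("NCh").  If
τ(N_i–Cα_i–C_i) > 112.5° **and** bump > 0.26 → NCh, else tc−; φ_i ≤ 0 →
nothing (normal prolines sit near φ = −60°).  Both inequalities are strict,
following the rule's published wording.

**cis→trans flag.**  Advisory only: a cis-modelled peptide is flagged when
Cα–Cα ≥ 3.2 Å (X-Xnpg) / 3.3 Å (X-Pro) or C–N–Cα ≥ 131° / 140°.  These are
midpoints between the reported medians of correct and misassigned cis
peptides, not validated cutoffs, and are labelled advisory in all reports.

## Synthetic data: what it emulates and what it does not

The builder places backbones by sequential internal-coordinate (NeRF)
construction with Engh–Huber-style parameters (N–Cα 1.458, Cα–C 1.525,
C–N 1.329, C=O 1.231 Å; Cα–C–N 116.2°; C–N–Cα 121.7° trans / 119.3°
trans-Pro / 125.0° cis / 127.0° cis-Pro; τ 111.0°; O=C–N such that
Cα–C–O = 120.8°).  At σ = 0 every spec torsion and angle is recovered
exactly by measurement.  These parameters put the ideal trans Cα–Cα
distance at 3.804 Å and the cis one at 2.84–2.89 Å.

**Flip operators.**  Real flips happen between two models fitted to the
same data, so the Cα trace must not move.  tt+/cc+ is the rigid rotation
of the plane unit (C2, O2, N3, Pro Cδ) by 180° about the Cα2–Cα3 axis
(self-inverse to machine precision).  A frame-held trans↔cis change is
different: forcing the other isomer inside a fixed Cα frame drives the
Cα2–C2–N3 angle towards 180° (the "almost straight" geometry seen in
wrinkled misassigned prolines), which makes torsions through that triple
numerically degenerate.  `apply_flip` therefore returns, for trans↔cis
codes, the refinement-relaxed form: ideal internal geometry rebuilt at the
flipped torsions and aligned back onto the original Cα frame.  Because of
the degeneracy, ψ angles of the frame-held intermediate are measured
through the carbonyl O (which spans the same plane without passing through
the degenerate triple) and ω is set to its known target rather than
measured.  With this construction the comparison procedure recovers all
five codes in 100/100 noise-free cases per residue class and ≥95% under
σ = 0.05 Å noise.

**Strain model.**  A misassigned example interpolates, atom by atom,
between the relaxed wrong conformation (λ = 0) and the exact frame-held
inverse flip of the truth (λ = 1); λ is thus the retained strain fraction.
This reproduces the reported deviation directions: trans-modelled cis
peptides shrink their Cα–Cα towards 2.9 Å and distort Cα–C–N; cis-modelled
trans peptides inflate Cα–Cα and C–N–Cα.  Plane atoms additionally get
λ-scaled B-factor elevation (O +25, C +15 Å² for tt+; +8–10 Å² for
trans↔cis), emulating the high plane-O B factors of flip candidates.
Backbones are sampled from a broad β-region (φ ∈ [−150°, −60°],
ψ ∈ [90°, 170°]; Pro φ ∈ [−75°, −55°]), ω jittered N(·, 2°), baseline B
uniform 15–40 Å², resolution uniform 1.0–2.5 Å.  Datasets default to
λ ∈ [0.7, 1] and σ = 0.05 Å — strongly strained, as appropriate for cases
worth flagging — and are deterministic under a single seed.

What the generator does **not** emulate: crystal packing and solvent
contacts (bump scores of isolated chains are ~0), real refinement
correlations between neighbouring residues, electron-density quality, and
the long tail of mild strain near λ→0.  Classifier results on this data
therefore demonstrate that the pipeline recovers planted signal at
realistic strain levels, not PDB-wide performance; published test-set
metrics are reproduced from the published confusion tables, never from
synthetic data.

## Classifiers

One binary Random Forest per (residue class, flip type), for the four
tasks with adequate real-world training data: X-Xnpg tc−, X-Xnpg tt+,
X-Gly tt+, X-Pro tc+ (cis→trans and other small categories are left to
the explicit rules).  Classes are balanced by downsampling; tt+ training
uses only examples at ≤ 2.2 Å (X-Gly < 2.0 Å), where plane assignment is
reliable and B factors reflect disorder rather than resolution.  The
ensemble has 500 trees; features-per-split is tuned over {√p, p/3, p/2}
by repeated stratified 5-fold cross-validation maximizing MCC (the
tuning grid is a package choice).  Per-flip classifiers combine by
highest-scoring positive verdict; exact ties break towards tt+ (the most
common correction) and are logged.  Everything is deterministic given the
seed.  Metrics: MCC (imbalance-robust), accuracy, and AUC via the
Mann–Whitney rank statistic with averaged ties.

## Numerical choices and degenerate inputs

Collinear torsion triples and zero-length angle arms raise errors naming
the problem; they are never silently patched.  MCC raises when a margin
is zero.  AUC requires both classes.  The builder rejects negative noise;
the strain model rejects λ outside [0, 1]; cc+ examples are refused by the
generator (representable geometrically, but absent from nature's
observations and untrainable).

## Experiment sizes

The acceptance experiments use 20 builds per flip code for round-trip
recovery, 1000 random cases for the geometry cross-check, and 2000
examples per classifier task (70/30 train/held-out split, tuning disabled
in favour of the √p default) — sizes at which every reported quantity is
stable under seed changes while the whole run stays around a minute.

## Known limitations

* The WH score is a surrogate; its numeric scale is not comparable to the
  original implementation's, so the 0.26 bump threshold and the WH
  thresholds should be recalibrated before quantitative use on real PDB
  entries.
* Secondary structure is 3-state and minimal (no π/3₁₀ distinction, no
  ladders/sheets bookkeeping); bridge detection is conservative.
* The strain surrogate is not re-refinement; how closely λ matches real
  PDB strain distributions is untestable without external data.
* Nitrogen-chirality cases are detected (NCh verdict), never repaired.
* Electron-density evidence — the final arbiter for real flips — is out
  of scope.
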