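# flipcheck

Detection of peptide bonds in protein crystal structures that need a
**peptide-plane flip** or a ***trans*↔*cis* flip**.

The peptide bond is planar, with the backbone torsion
ω (Cα<sub>i−1</sub>—C<sub>i−1</sub>—N<sub>i</sub>—Cα<sub>i</sub>) near 180°
(*trans*) or 0° (*cis*).  Because *trans* is energetically preferred and
model-building software tries it first, genuinely *cis* peptides are often
deposited as *trans*, and entire peptide planes are sometimes built inverted.
A misassigned plane leaves a geometric fingerprint: strained backbone angles,
a Cα–Cα distance pulled towards the other isomer, and elevated B factors on
the plane atoms.  `flipcheck` computes these descriptors per tetrapeptide
(four consecutive residues around a central peptide bond), applies the
published explicit decision rules, and trains Random Forest classifiers to
flag planes in need of correction.

It is aimed at crystallographers validating or re-refining structure models,
and at developers of validation pipelines.

## Flip codes

A conformational change between two models of the same protein is coded with
two letters (t/c — the isomer before and after) and a sign: `+` when the
backbone carbonyl C=O flips, `−` when it does not (for *trans*↔*cis* changes
the amide N—H flips instead):

| code | change | what moves |
|------|--------|------------|
| tt+  | peptide-plane flip | C=O and N—H invert, ω stays *trans* |
| tc− / ct− | *trans*↔*cis* | N—H flips, C=O kept |
| tc+ / ct+ | *trans*↔*cis* | C=O flips, N—H kept |
| tt− / cc− | none (correct) | — |

Pairwise assignment uses three variables measured after superposing the two
tetrapeptides on their four Cα atoms: the (C=O, C=O) angle, the (N—H, N—H)
angle (N→Cδ for proline) and the ω difference.

## What is implemented

* exact geometry primitives (distances, angles, IUPAC torsions, chiral
  volumes, Kabsch superposition);
* PDB/mmCIF reading (via gemmi) with the entry- and residue-level selection
  rules (X-ray, ≤3.5 Å, canonical complete residues, full occupancy, B > 0,
  no alternate locations, no chain breaks, no disulfides, no foreign atom
  within 2.5 Å of the central carbonyl O);
* the per-tetrapeptide feature set: Cα–Cα / Cβ–Cβ / O–O distances, backbone
  torsions and bond angles, chiral volumes, C–O–C–O pseudo-torsions, the
  carbonyl-O bump score, a minimal Kabsch–Sander 3-state secondary
  structure, carbonyl–helix alignment, B factors, and the Weiss–Hilgenfeld
  penalty score D<sub>tot</sub> (thresholds 143.10 / 82.256);
* the X-Pro positive-φ decision tree (τ > 112.5° and bump > 0.26 →
  nitrogen-chirality problem, otherwise tc−) and the *cis*→*trans*
  candidate flag;
* a synthetic-data module that builds ideal-geometry tetrapeptides
  (Engh–Huber-style parameters), applies every flip code, and emulates the
  residual strain of misassigned peptides, so that all classifiers are
  trainable and testable without any downloads;
* per-residue-class, per-flip-type Random Forest classifiers with repeated
  stratified 5-fold cross-validation, class balancing, resolution windows
  (tt+ ≤ 2.2 Å, X-Gly tt+ < 2.0 Å) and combination into one verdict per
  residue class; metrics: MCC, accuracy, rank-statistic AUC.

## Worked example

Plant a strained trans-modelled peptide (that is really *cis*) in a
synthetic chain and check it:

```python
from flipcheck.structure import write_pdb
from flipcheck.synthetic import BuildSpec, build_tetrapeptide, make_strained_example, embed_example

truth = build_tetrapeptide(BuildSpec(omega=0.0, first_seqnum=10))   # true cis
ex = make_strained_example(truth, "tc-", lam=0.9, sigma=0.02, seed=2)
write_pdb(embed_example(ex.tetrapeptide, n_flank=3), "planted.pdb")
```

```text
$ flipcheck check planted.pdb
chain  resnum  restype_prev  restype  residue_class  omega   ca_ca  wh_dtot  wh_verdict  ...
A      9       ALA           ALA      X-Xnpg         180.0   3.74   1.81     no-flip
A      10      ALA           SER      X-Xnpg         -177.3  3.79   2.85     no-flip
A      11      SER           LEU      X-Xnpg         -177.2  2.96   1672.84  flip
A      12      LEU           ALA      X-Xnpg         179.8   3.81   5.97     no-flip
A      13      ALA           ALA      X-Xnpg         -180.0  3.76   0.75     no-flip
```

Only the planted bond (Ser11–Leu12) is flagged: its ω is *trans* but the
Cα–Cα distance (2.96 Å) is at the *cis* value, so the Weiss–Hilgenfeld
penalty explodes past the 82.256 cutoff.  With trained classifiers
(`--models <dir>`) the same row gets `rf_verdict: tc-` with score 0.93.

Comparing two models of the same protein assigns flip codes per shared
tetrapeptide:

```text
$ flipcheck compare modelA.pdb modelB.pdb
chain  resnum  restype_prev  restype  omega_a  omega_b  co_angle  nh_angle  flip_code
A      11      SER           LEU      180.0    180.0    159.4     151.7     tt+
...
```

The other subcommands are `simulate` (labelled synthetic datasets),
`train` and `eval`; see `flipcheck --help`.

## Layout

```
src/flipcheck/
  geometry.py      3D primitives and internal-coordinate placement
  structure.py     PDB/mmCIF models, selection filters, tetrapeptides
  conformation.py  cis/trans/twisted, amide H, pairwise flip assignment
  features.py      descriptor set, bump score, secondary structure, WH score
  rules.py         X-Pro positive-φ tree, cis→trans flag
  synthetic.py     ideal builder, flip operators, strain model, datasets
  classify.py      Random Forests, CV, metrics, combination
  experiments.py   reproducible end-to-end experiments
  cli.py           check / compare / simulate / train / eval
docs/methods.md    model, assumptions, parameter choices, limitations
```
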