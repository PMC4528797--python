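"""Ideal-geometry peptide builder, flip operators and labelled-dataset
generator.

Backbones are constructed by sequential internal-coordinate placement
using Engh–Huber-style reference bond lengths and angles, so that every
directly-built torsion and angle is recovered exactly by measurement.
Flip operators apply the rigid rotations that define each flip code, and
``make_strained_example`` emulates the residual strain that refinement
restraints leave in a peptide modelled in the wrong conformation — the
training signal that real misassigned peptides carry.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    bond_angle,
    dihedral_angle,
    place_atom,
    rotation_about_axis,
    wrap_angle,
)
from .structure import AtomRecord, Residue, StructureModel, Tetrapeptide

FLIPPABLE = ("tt+", "tc-", "tc+", "ct-", "ct+")
CORRECT = ("tt-", "cc-")

_INVERSE = {"tt+": "tt+", "tc-": "ct-", "ct-": "tc-", "tc+": "ct+", "ct+": "tc+", "cc+": "cc+"}


@dataclass
class IdealParams:
    """Engh–Huber-style reference geometry (Å, degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.530
    n_cd: float = 1.473
    ca_c_n: float = 116.2
    c_n_ca_trans: float = 121.7
    c_n_ca_trans_pro: float = 119.3
    c_n_ca_cis: float = 125.0
    c_n_ca_cis_pro: float = 127.0
    tau: float = 111.0
    ca_c_o: float = 120.8
    n_ca_cb: float = 110.5
    cb_improper: float = -122.6  # torsion C–N–Cα–Cβ giving L chirality

    def c_n_ca(self, next_residue: str, omega: float) -> float:
        cis = abs(wrap_angle(omega)) < 90.0
        if next_residue == "PRO":
            return self.c_n_ca_cis_pro if cis else self.c_n_ca_trans_pro
        return self.c_n_ca_cis if cis else self.c_n_ca_trans


@dataclass
class BuildSpec:
    """Recipe for one ideal-geometry tetrapeptide."""

    residues: tuple[str, str, str, str] = ("ALA", "SER", "LEU", "ALA")
    phi: tuple[float, ...] = (-120.0, -120.0, -120.0, -120.0)
    psi: tuple[float, ...] = (140.0, 140.0, 140.0, 140.0)
    omega: float = 180.0          # central bond (residues 2–3)
    omega_prev: float = 180.0
    omega_next: float = 180.0
    params: IdealParams = field(default_factory=IdealParams)
    angle_overrides: dict = field(default_factory=dict)
    sigma: float = 0.0            # Å coordinate noise
    seed: int = 0
    b_base: float = 20.0
    b_offsets: dict = field(default_factory=dict)  # (res_index, atom) -> ΔB
    resolution: float = 2.0
    chain_id: str = "A"
    first_seqnum: int = 2

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def build_tetrapeptide(spec: BuildSpec) -> Tetrapeptide:
    """Construct a tetrapeptide by internal-coordinate chaining.

    At σ=0 every spec torsion and bond angle is recovered exactly by
    measurement on the result.
    """
    p = spec.params
    ov = spec.angle_overrides
    rng = np.random.default_rng(spec.seed)

    # seed atoms of residue 1 in the xy-plane
    pos: dict[tuple[int, str], np.ndarray] = {}
    tau1 = ov.get("tau1", p.tau)
    pos[(0, "N")] = np.zeros(3)
    pos[(0, "CA")] = np.array([p.n_ca, 0.0, 0.0])
    t = np.radians(tau1)
    pos[(0, "C")] = pos[(0, "CA")] + p.ca_c * np.array([-np.cos(t), np.sin(t), 0.0])

    omegas = (spec.omega_prev, spec.omega, spec.omega_next)
    for i in range(3):  # bond between residues i and i+1
        n_res = spec.residues[i + 1]
        c_n_ca = p.c_n_ca(n_res, omegas[i])
        ca_c_n = p.ca_c_n
        tau_next = p.tau
        if i == 1:  # central bond: overridable strained geometry
            ca_c_n = ov.get("ca2_c2_n3", ca_c_n)
            c_n_ca = ov.get("c2_n3_ca3", c_n_ca)
            tau_next = ov.get("tau3", tau_next)
        elif i == 0:
            tau_next = ov.get("tau2", tau_next)
        pos[(i + 1, "N")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], p.c_n, ca_c_n, spec.psi[i]
        )
        pos[(i + 1, "CA")] = place_atom(
            pos[(i, "CA")], pos[(i, "C")], pos[(i + 1, "N")], p.n_ca, c_n_ca, omegas[i]
        )
        pos[(i + 1, "C")] = place_atom(
            pos[(i, "C")], pos[(i + 1, "N")], pos[(i + 1, "CA")],
            p.ca_c, tau_next, spec.phi[i + 1],
        )

    for i in range(4):
        ca_c_o = ov.get("ca2_c2_o2", p.ca_c_o) if i == 1 else p.ca_c_o
        pos[(i, "O")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
            p.c_o, ca_c_o, spec.psi[i] + 180.0,
        )
        if spec.residues[i] != "GLY":
            pos[(i, "CB")] = place_atom(
                pos[(i, "C")], pos[(i, "N")], pos[(i, "CA")],
                p.ca_cb, p.n_ca_cb, p.cb_improper,
            )
        if spec.residues[i] == "PRO" and i > 0:
            n = pos[(i, "N")]
            u = pos[(i - 1, "C")] - n
            v = pos[(i, "CA")] - n
            d = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            pos[(i, "CD")] = n + p.n_cd * d / np.linalg.norm(d)

    residues = []
    for i in range(4):
        atoms = []
        for name in ("N", "CA", "C", "O", "CB", "CD"):
            if (i, name) not in pos:
                continue
            xyz = pos[(i, name)]
            if spec.sigma > 0:
                xyz = xyz + rng.normal(0.0, spec.sigma, size=3)
            b = spec.b_base + spec.b_offsets.get((i, name), 0.0)
            atoms.append(
                AtomRecord(name=name, element=name[0], position=np.asarray(xyz, float),
                           b_factor=b, occupancy=1.0)
            )
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                seqnum=spec.first_seqnum + i,
                icode="",
                name=spec.residues[i],
                atoms=atoms,
            )
        )
    return Tetrapeptide(residues=tuple(residues), entry_id="SYNTH",
                        resolution=spec.resolution)


def as_structure(t: Tetrapeptide, entry_id: str = "SYNTH") -> StructureModel:
    """Wrap a tetrapeptide as a single-chain StructureModel."""
    return StructureModel(
        entry_id=entry_id,
        method="X-RAY DIFFRACTION",
        resolution=t.resolution,
        chains={t[0].chain_id: list(t.residues)},
    )


def _copy(t: Tetrapeptide) -> Tetrapeptide:
    return copy.deepcopy(t)


def _conformation_symbol(t: Tetrapeptide) -> str:
    from .conformation import backbone_torsions, peptide_conformation

    conf = peptide_conformation(backbone_torsions(t).omega_central)
    return {"trans": "t", "cis": "c"}.get(conf, "?")


def _rotate_atoms(t: Tetrapeptide, selector, origin, axis) -> None:
    rot = rotation_about_axis(origin, axis, 180.0)
    for i, res in enumerate(t.residues):
        for a in res.atoms:
            if selector(i, a.name):
                a.position = rot(a.position)


def apply_flip(t: Tetrapeptide, code: str, relax: bool = True) -> Tetrapeptide:
    """Apply a flip to the central peptide bond; returns a new tetrapeptide.

    All operations move only central-plane atoms and keep the Cα trace
    fixed, as in a real flip between two models fitted to the same X-ray
    data (the plane inverts; the fold does not move):

    * tt+/cc+ — rotate the plane unit (C2, O2, N3, Pro Cδ) 180° about the
      Cα2→Cα3 axis: ω keeps its isomer, C=O and N–H both invert.
    * tc−/ct− — rotate N3 (and Cδ) 180° about the C2→Cα3 axis: ω crosses
      between trans and cis, C=O is unchanged, N–H inverts.
    * tc+/ct+ — compose the two (plane rotation then N3 rotation for tc+,
      the reverse order for ct+): ω crosses, C=O inverts, and the N–H
      inversion of each component cancels.

    For tt+/cc+ the rigid rotation is returned as-is (it preserves ideal
    geometry, and applying it twice restores the original coordinates
    exactly).  A frame-held trans↔cis change, in contrast, is heavily
    strained — the four-atom ω chain nearly straightens — so for the
    trans↔cis codes the flipped model is relaxed: rebuilt with ideal
    internal geometry at the flipped torsions and aligned back onto the
    original Cα frame, as refinement would leave it.  Pass
    ``relax=False`` to obtain the raw frame-held coordinates.
    """
    if code not in _INVERSE:
        raise ValueError(f"unknown flip code {code!r}")
    if _conformation_symbol(t) != code[0]:
        raise ValueError(
            f"conformation mismatch: flip {code} requires a {code[0]!r} start"
        )
    out = _frame_held_flip(t, code)
    if relax and code not in ("tt+", "cc+"):
        from .conformation import backbone_torsions

        omega_target = wrap_angle(backbone_torsions(t).omega_central + 180.0)
        relaxed = _relaxed_rebuild(out, BuildSpec(), omega_target)
        for res_out, res_t in zip(relaxed.residues, t.residues):
            for a in res_out.atoms:
                src = res_t.atom(a.name)
                if src is not None:
                    a.b_factor = src.b_factor
        return relaxed
    return out


def _frame_held_flip(t: Tetrapeptide, code: str) -> Tetrapeptide:
    out = _copy(t)
    if code in ("tt+", "cc+"):
        _plane_rotation(out)
    elif code in ("tc-", "ct-"):
        _nh_rotation(out)
    elif code == "tc+":
        _plane_rotation(out)
        _nh_rotation(out)
    else:  # ct+
        _nh_rotation(out)
        _plane_rotation(out)
    return out


def _plane_rotation(t: Tetrapeptide) -> None:
    origin = t.pos(1, "CA")
    axis = t.pos(2, "CA") - origin

    def sel(i, name):
        return (i == 1 and name in ("C", "O")) or (i == 2 and name in ("N", "CD"))

    _rotate_atoms(t, sel, origin, axis)


def _nh_rotation(t: Tetrapeptide) -> None:
    origin = t.pos(1, "C")
    axis = t.pos(2, "CA") - origin

    def sel(i, name):
        return i == 2 and name in ("N", "CD")

    _rotate_atoms(t, sel, origin, axis)


def _co_rotation(t: Tetrapeptide) -> None:
    origin = t.pos(1, "CA")
    axis = t.pos(2, "N") - origin

    def sel(i, name):
        return i == 1 and name in ("C", "O")

    _rotate_atoms(t, sel, origin, axis)


@dataclass
class LabelledExample:
    tetrapeptide: Tetrapeptide
    label: str              # flip needed, or "tt-"/"cc-" for correct peptides
    residue_class: str
    lam: float
    sigma: float
    seed: int
    truth: Tetrapeptide | None = None


def _relaxed_rebuild(
    raw: Tetrapeptide, base: BuildSpec, omega_target: float
) -> Tetrapeptide:
    """Rebuild a frame-held mis-flipped model with ideal internal geometry
    at its measured backbone torsions, aligned onto the raw Cα frame —
    the conformation refinement restraints relax towards.

    A frame-held trans↔cis flip drives the Cα2–C2–N3 angle towards 180°,
    which makes torsions through that triple (ω, N-based ψ2) numerically
    unstable, so ψ angles are measured through the carbonyl O (which
    defines the same plane without the degeneracy) and ω is set to the
    known flip target rather than measured.
    """
    from .geometry import apply_transform, superpose

    p = raw.pos

    def psi_from_o(i: int) -> float:
        return wrap_angle(
            dihedral_angle(p(i, "N"), p(i, "CA"), p(i, "C"), p(i, "O")) - 180.0
        )

    phi2 = dihedral_angle(p(0, "C"), p(1, "N"), p(1, "CA"), p(1, "C"))
    phi3 = dihedral_angle(p(1, "C"), p(2, "N"), p(2, "CA"), p(2, "C"))
    phi4 = dihedral_angle(p(2, "C"), p(3, "N"), p(3, "CA"), p(3, "C"))
    omega_prev = dihedral_angle(p(0, "CA"), p(0, "C"), p(1, "N"), p(1, "CA"))
    omega_next = dihedral_angle(p(2, "CA"), p(2, "C"), p(3, "N"), p(3, "CA"))
    spec = replace(
        base,
        residues=tuple(r.name for r in raw.residues),
        phi=(base.phi[0], phi2, phi3, phi4),
        psi=(psi_from_o(0), psi_from_o(1), psi_from_o(2), psi_from_o(3)),
        omega=omega_target,
        omega_prev=omega_prev,
        omega_next=omega_next,
        angle_overrides={},
        sigma=0.0,
        first_seqnum=raw[0].seqnum,
        chain_id=raw[0].chain_id,
        resolution=raw.resolution,
    )
    rel = build_tetrapeptide(spec)
    ca_rel = np.array([rel.pos(i, "CA") for i in range(4)])
    ca_raw = np.array([raw.pos(i, "CA") for i in range(4)])
    rot, trans, _ = superpose(ca_rel, ca_raw)
    for res in rel.residues:
        for a in res.atoms:
            a.position = apply_transform(a.position, rot, trans)
    return rel


# extra B (Å²) given to the central-plane C and O at full strain: planes
# modelled in the wrong conformation refine to elevated B factors, most
# prominently for peptide-plane (tt+) flips
_B_STRAIN = {"tt+": (15.0, 25.0), "tc-": (10.0, 10.0), "tc+": (10.0, 10.0),
             "ct-": (8.0, 8.0), "ct+": (8.0, 8.0)}


def make_strained_example(
    truth: Tetrapeptide,
    needed: str,
    lam: float,
    sigma: float = 0.0,
    seed: int = 0,
    spec: BuildSpec | None = None,
) -> LabelledExample:
    """Emulate a peptide modelled in the wrong conformation.

    *truth* is the correct conformation.  The misassigned model is built
    by applying the inverse flip to the central plane with the Cα frame
    held fixed (maximal strain: the data win everywhere except the plane
    itself), then interpolating every atom towards the geometrically
    relaxed wrong conformation.  λ is the retained strain fraction: λ=1 →
    the exact frame-held inverse flip, λ=0 → ideal internal geometry in
    the wrong conformation.  Gaussian coordinate noise σ and λ-scaled
    B-factor elevation of the plane atoms are applied last; the label is
    the flip *needed* to correct the model.
    """
    from .structure import residue_class as _rc

    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if needed not in FLIPPABLE:
        raise ValueError(f"unsupported flip code {needed!r}")
    rng = np.random.default_rng(seed)
    base = spec or BuildSpec()
    from .conformation import backbone_torsions

    omega_truth = backbone_torsions(truth).omega_central
    omega_target = (
        omega_truth if needed in ("tt+", "cc+") else wrap_angle(omega_truth + 180.0)
    )
    raw = _frame_held_flip(truth, _INVERSE[needed])
    rel = _relaxed_rebuild(raw, base, omega_target)

    model = _copy(raw)
    b_c, b_o = _B_STRAIN[needed]
    for res_raw, res_rel, res_out in zip(raw.residues, rel.residues, model.residues):
        for a_out in res_out.atoms:
            a_raw = res_raw.atom(a_out.name)
            a_rel = res_rel.atom(a_out.name)
            if a_rel is None:  # atom absent from rebuild (shouldn't happen)
                continue
            pos = lam * a_raw.position + (1.0 - lam) * a_rel.position
            if sigma > 0:
                pos = pos + rng.normal(0.0, sigma, size=3)
            a_out.position = pos
            a_out.b_factor = base.b_base
    c2 = model[1].atom("C")
    o2 = model[1].atom("O")
    c2.b_factor += b_c * lam
    o2.b_factor += b_o * lam
    return LabelledExample(
        tetrapeptide=model, label=needed, residue_class=_rc(truth),
        lam=lam, sigma=sigma, seed=seed, truth=truth,
    )


_X_NAMES = ("ALA", "SER", "VAL", "LEU", "THR", "ASP", "PHE", "ASN")


def _sample_spec(rng: np.random.Generator, residue_class: str, cis: bool) -> BuildSpec:
    """Random realistic build spec: β-region backbone, jittered ω,
    resolution and baseline B sampled per example."""
    res3 = {"X-Pro": "PRO", "X-Gly": "GLY"}.get(residue_class)
    residues = tuple(
        res3 if (i == 2 and res3) else _X_NAMES[rng.integers(len(_X_NAMES))]
        for i in range(4)
    )
    phi = tuple(float(rng.uniform(-150, -60)) for _ in range(4))
    psi = tuple(float(rng.uniform(90, 170)) for _ in range(4))
    if residues[2] == "PRO":
        phi = phi[:2] + (float(rng.uniform(-75, -55)),) + phi[3:]
    omega = float(rng.normal(0.0 if cis else 180.0, 2.0))
    return BuildSpec(
        residues=residues,
        phi=phi,
        psi=psi,
        omega=wrap_angle(omega),
        omega_prev=float(rng.normal(180, 2)),
        omega_next=float(rng.normal(180, 2)),
        b_base=float(rng.uniform(15, 40)),
        resolution=float(rng.uniform(1.0, 2.5)),
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_labeled_dataset(
    counts: dict[tuple[str, str], int],
    lam_range: tuple[float, float] = (0.7, 1.0),
    sigma: float = 0.05,
    seed: int = 0,
) -> list[LabelledExample]:
    """Balanced labelled examples per (residue class, label) request.

    Labels "tt-"/"cc-" produce correct peptides built directly in the
    stated conformation; flip labels produce strained misassigned models
    with λ drawn uniformly from *lam_range*.  Deterministic under *seed*.
    """
    rng = np.random.default_rng(seed)
    out: list[LabelledExample] = []
    for (rc, label), n in counts.items():
        if n <= 0:
            raise ValueError("counts must be positive")
        if label == "cc+" or label not in FLIPPABLE + CORRECT:
            raise ValueError(f"unsupported class/flip combination: {rc}/{label}")
        for _ in range(n):
            if label in CORRECT:
                spec = _sample_spec(rng, rc, cis=label.startswith("c"))
                spec = replace(spec, sigma=sigma)
                t = build_tetrapeptide(spec)
                out.append(
                    LabelledExample(
                        tetrapeptide=t, label=label, residue_class=rc,
                        lam=0.0, sigma=sigma, seed=spec.seed,
                    )
                )
            else:
                truth_cis = label[1] == "c"  # truth = corrected conformation
                spec = _sample_spec(rng, rc, cis=truth_cis)
                truth = build_tetrapeptide(replace(spec, sigma=0.0))
                lam = float(rng.uniform(*lam_range))
                out.append(
                    make_strained_example(
                        truth, label, lam, sigma=sigma,
                        seed=int(rng.integers(2**31 - 1)), spec=spec,
                    )
                )
    return out


def write_dataset(examples: list[LabelledExample], outdir) -> None:
    """Serialize a dataset as PDB fixture files plus a TSV label manifest."""
    from pathlib import Path

    from .structure import write_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["path\tclass\tlabel\tlambda\tsigma\tseed\tresolution"]
    for k, ex in enumerate(examples):
        name = f"example_{k:05d}.pdb"
        write_pdb(as_structure(ex.tetrapeptide, entry_id=f"S{k:04d}"), outdir / name)
        lines.append(
            f"{name}\t{ex.residue_class}\t{ex.label}\t{ex.lam:.4f}"
            f"\t{ex.sigma:.4f}\t{ex.seed}\t{ex.tetrapeptide.resolution}"
        )
    (outdir / "labels.tsv").write_text("\n".join(lines) + "\n")


def build_chain(
    residues: list[str],
    phi: float | list[float] = -57.0,
    psi: float | list[float] = -47.0,
    omega: float = 180.0,
    params: IdealParams | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    b_base: float = 20.0,
    resolution: float = 2.0,
    chain_id: str = "A",
    first_seqnum: int = 1,
    origin: np.ndarray | None = None,
) -> list[Residue]:
    """Ideal-geometry chain of arbitrary length (α-helix by default).

    Used to build secondary-structure fixtures (helices, strands) and
    multi-window synthetic chains; per-residue φ/ψ may be scalars or
    lists.  Returns a list of Residues; wrap with ``chain_structure``.
    """
    n = len(residues)
    p = params or IdealParams()
    rng = np.random.default_rng(seed)
    phis = [phi] * n if np.isscalar(phi) else list(phi)
    psis = [psi] * n if np.isscalar(psi) else list(psi)

    pos: dict[tuple[int, str], np.ndarray] = {}
    shift = origin if origin is not None else np.zeros(3)
    pos[(0, "N")] = np.zeros(3) + shift
    pos[(0, "CA")] = np.array([p.n_ca, 0.0, 0.0]) + shift
    tt = np.radians(p.tau)
    pos[(0, "C")] = pos[(0, "CA")] + p.ca_c * np.array([-np.cos(tt), np.sin(tt), 0.0])
    for i in range(n - 1):
        pos[(i + 1, "N")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], p.c_n, p.ca_c_n, psis[i]
        )
        pos[(i + 1, "CA")] = place_atom(
            pos[(i, "CA")], pos[(i, "C")], pos[(i + 1, "N")],
            p.n_ca, p.c_n_ca(residues[i + 1], omega), omega,
        )
        pos[(i + 1, "C")] = place_atom(
            pos[(i, "C")], pos[(i + 1, "N")], pos[(i + 1, "CA")],
            p.ca_c, p.tau, phis[i + 1],
        )
    for i in range(n):
        pos[(i, "O")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], p.c_o, p.ca_c_o,
            psis[i] + 180.0,
        )
        if residues[i] != "GLY":
            pos[(i, "CB")] = place_atom(
                pos[(i, "C")], pos[(i, "N")], pos[(i, "CA")],
                p.ca_cb, p.n_ca_cb, p.cb_improper,
            )
        if residues[i] == "PRO" and i > 0:
            nn = pos[(i, "N")]
            u = pos[(i - 1, "C")] - nn
            v = pos[(i, "CA")] - nn
            d = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            pos[(i, "CD")] = nn + p.n_cd * d / np.linalg.norm(d)

    out = []
    for i in range(n):
        atoms = []
        for name in ("N", "CA", "C", "O", "CB", "CD"):
            if (i, name) not in pos:
                continue
            xyz = pos[(i, name)]
            if sigma > 0:
                xyz = xyz + rng.normal(0.0, sigma, size=3)
            atoms.append(
                AtomRecord(name=name, element=name[0], position=np.asarray(xyz, float),
                           b_factor=b_base, occupancy=1.0)
            )
        out.append(
            Residue(chain_id=chain_id, seqnum=first_seqnum + i, icode="",
                    name=residues[i], atoms=atoms)
        )
    return out


def chain_structure(
    residue_lists: list[list[Residue]] | list[Residue],
    entry_id: str = "SYNTH",
    resolution: float = 2.0,
) -> StructureModel:
    """StructureModel from one or several built chains."""
    if residue_lists and isinstance(residue_lists[0], Residue):
        residue_lists = [residue_lists]
    chains = {rs[0].chain_id: list(rs) for rs in residue_lists}
    return StructureModel(
        entry_id=entry_id, method="X-RAY DIFFRACTION",
        resolution=resolution, chains=chains,
    )


def embed_example(
    t: Tetrapeptide,
    n_flank: int = 2,
    flank_phi: float = -120.0,
    flank_psi: float = 140.0,
    flank_name: str = "ALA",
    entry_id: str = "SYNTH",
) -> StructureModel:
    """Embed a tetrapeptide in a longer chain by extending both ends with
    ideal trans residues, preserving the window geometry exactly.

    The result passes the terminus/chain-break selection rules for the
    embedded window, so planted defects survive tetrapeptide extraction.
    """
    p = IdealParams()
    first = t.residues[0]
    last = t.residues[-1]

    def res_from(pos: dict[str, np.ndarray], seqnum: int) -> Residue:
        atoms = [
            AtomRecord(name=name, element=name[0], position=xyz.copy(),
                       b_factor=20.0, occupancy=1.0)
            for name, xyz in pos.items()
        ]
        return Residue(chain_id=first.chain_id, seqnum=seqnum, icode="",
                       name=flank_name, atoms=atoms)

    # forward extension: continue from the last residue, keeping its O
    # anti to the new amide N (implied psi from the O position)
    before: list[Residue] = []
    after: list[Residue] = []
    n_i, ca_i, c_i = last.pos("N"), last.pos("CA"), last.pos("C")
    psi_i = wrap_angle(
        dihedral_angle(n_i, ca_i, c_i, last.pos("O")) - 180.0
    )
    for k in range(n_flank):
        n_new = place_atom(n_i, ca_i, c_i, p.c_n, p.ca_c_n, psi_i)
        ca_new = place_atom(ca_i, c_i, n_new, p.n_ca, p.c_n_ca_trans, 180.0)
        c_new = place_atom(c_i, n_new, ca_new, p.ca_c, p.tau, flank_phi)
        o_new = place_atom(n_new, ca_new, c_new, p.c_o, p.ca_c_o, flank_psi + 180.0)
        cb_new = place_atom(c_new, n_new, ca_new, p.ca_cb, p.n_ca_cb, p.cb_improper)
        after.append(res_from(
            {"N": n_new, "CA": ca_new, "C": c_new, "O": o_new, "CB": cb_new},
            last.seqnum + 1 + k,
        ))
        n_i, ca_i, c_i = n_new, ca_new, c_new
        psi_i = flank_psi

    # backward extension by reverse internal-coordinate chaining
    n1, ca1, c1 = first.pos("N"), first.pos("CA"), first.pos("C")
    phi_1 = flank_phi
    for k in range(n_flank):
        c_prev = place_atom(c1, ca1, n1, p.c_n, p.c_n_ca_trans, phi_1)
        ca_prev = place_atom(ca1, n1, c_prev, p.ca_c, p.ca_c_n, 180.0)
        n_prev = place_atom(n1, c_prev, ca_prev, p.n_ca, p.tau, flank_psi)
        o_prev = place_atom(n_prev, ca_prev, c_prev, p.c_o, p.ca_c_o, flank_psi + 180.0)
        cb_prev = place_atom(c_prev, n_prev, ca_prev, p.ca_cb, p.n_ca_cb, p.cb_improper)
        before.append(res_from(
            {"N": n_prev, "CA": ca_prev, "C": c_prev, "O": o_prev, "CB": cb_prev},
            first.seqnum - 1 - k,
        ))
        n1, ca1, c1 = n_prev, ca_prev, c_prev
        phi_1 = flank_phi

    chain = list(reversed(before)) + [copy.deepcopy(r) for r in t.residues] + after
    return StructureModel(
        entry_id=entry_id,
        method="X-RAY DIFFRACTION",
        resolution=t.resolution,
        chains={first.chain_id: chain},
    )
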