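"""Cis/trans/twisted assignment, amide-hydrogen inference and pairwise
flip-code assignment between corresponding tetrapeptides of two models.

Flip codes: two letters (t/c) give the conformation before and after the
change; the trailing sign is '+' when the backbone carbonyl C=O flips and
'−' (written '-') when it does not — for trans↔cis changes a '−' means
the amide N–H flipped instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .geometry import dihedral_angle, superpose, apply_transform, vector_angle, wrap_angle
from .structure import Tetrapeptide

FLIP_CODES = ("tt-", "tt+", "tc-", "tc+", "cc-", "cc+", "ct-", "ct+")


@dataclass
class BackboneTorsions:
    omega_central: float
    phi2: float | None
    psi2: float
    phi3: float
    psi3: float | None
    omega_prev: float | None
    omega_next: float | None


@dataclass
class PeptideComparison:
    co_angle: float
    nh_angle: float
    delta_omega: float
    omega_a: float
    omega_b: float
    flip: str  # a FLIP_CODES member or "indeterminate"


def backbone_torsions(t: Tetrapeptide) -> BackboneTorsions:
    """Backbone torsions around the central peptide bond.

    ω(central) = Cα2–C2–N3–Cα3, φ3 = C2–N3–Cα3–C3, ψ2 = N2–Cα2–C2–N3;
    flanking φ2/ψ3 and the neighbouring ω torsions use atoms of residues
    1 and 4.
    """
    p = t.pos
    omega = dihedral_angle(p(1, "CA"), p(1, "C"), p(2, "N"), p(2, "CA"))
    psi2 = dihedral_angle(p(1, "N"), p(1, "CA"), p(1, "C"), p(2, "N"))
    phi3 = dihedral_angle(p(1, "C"), p(2, "N"), p(2, "CA"), p(2, "C"))
    phi2 = dihedral_angle(p(0, "C"), p(1, "N"), p(1, "CA"), p(1, "C"))
    psi3 = dihedral_angle(p(2, "N"), p(2, "CA"), p(2, "C"), p(3, "N"))
    omega_prev = dihedral_angle(p(0, "CA"), p(0, "C"), p(1, "N"), p(1, "CA"))
    omega_next = dihedral_angle(p(2, "CA"), p(2, "C"), p(3, "N"), p(3, "CA"))
    return BackboneTorsions(
        omega_central=omega,
        phi2=phi2,
        psi2=psi2,
        phi3=phi3,
        psi3=psi3,
        omega_prev=omega_prev,
        omega_next=omega_next,
    )


def peptide_conformation(omega: float, cfg: RunConfig | None = None) -> str:
    """Classify ω into 'cis', 'trans' or 'twisted'.

    Twisted intermediates (ω near ±90°) arise when refinement restraints
    leave a peptide halfway between the two isomers; they must not be
    silently binned into either state.
    """
    cfg = cfg or RunConfig()
    if abs(omega) <= cfg.cis_max:
        return "cis"
    if abs(omega) >= cfg.trans_min:
        return "trans"
    return "twisted"


def infer_amide_hydrogen(t: Tetrapeptide) -> np.ndarray | None:
    """Idealized amide H on N3: 1.0 Å from N, in the C2–N3–Cα3 plane,
    opposite the bisector of N→C2 and N→Cα3.  Returns None for Pro
    (no amide H); callers substitute the N→Cδ direction.
    """
    if t[2].name == "PRO":
        return None
    n = t.pos(2, "N")
    u = t.pos(1, "C") - n
    v = t.pos(2, "CA") - n
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = -(u + v)
    nd = np.linalg.norm(d)
    if nd < 1e-8:
        raise ValueError("degenerate amide geometry")
    return n + d / nd


def amide_direction(t: Tetrapeptide) -> np.ndarray:
    """Unit vector of the central N–H bond, or N→Cδ for Pro."""
    n = t.pos(2, "N")
    if t[2].name == "PRO":
        if not t[2].has("CD"):
            raise ValueError("Pro residue lacks CD atom for N-H surrogate")
        d = t.pos(2, "CD") - n
    else:
        d = infer_amide_hydrogen(t) - n
    return d / np.linalg.norm(d)


def carbonyl_direction(t: Tetrapeptide) -> np.ndarray:
    d = t.pos(1, "O") - t.pos(1, "C")
    return d / np.linalg.norm(d)


def assign_flip_code(
    conf_a: str,
    conf_b: str,
    co_angle: float,
    nh_angle: float,
    cfg: RunConfig | None = None,
) -> str:
    """Flip code from the two conformations and the plane-vector angles.

    First symbol = conformation in model A, second = in model B; '+' when
    the (C=O, C=O) angle exceeds the separatrix (default 90°).  Twisted
    conformations, and same-conformation pairs whose N–H flipped without
    a C=O flip, are geometrically inconsistent → "indeterminate".
    """
    cfg = cfg or RunConfig()
    if conf_a == "twisted" or conf_b == "twisted":
        return "indeterminate"
    co_flipped = co_angle > cfg.co_flip_angle
    if conf_a == conf_b and not co_flipped and nh_angle > 90.0:
        return "indeterminate"
    sign = "+" if co_flipped else "-"
    return f"{conf_a[0]}{conf_b[0]}{sign}"


def compare_pair(
    a: Tetrapeptide, b: Tetrapeptide, cfg: RunConfig | None = None
) -> PeptideComparison:
    """Compare the central peptide planes of the same tetrapeptide in two
    models and assign the flip code.

    Model b is superposed onto model a on the four Cα atoms; the three
    descriptors are the (C=O, C=O) angle, the (N–H, N–H) angle (N→Cδ for
    Pro) and the wrapped ω difference.
    """
    cfg = cfg or RunConfig()
    for ra, rb in zip(a.residues, b.residues):
        if (ra.chain_id, ra.seqnum, ra.icode, ra.name) != (
            rb.chain_id,
            rb.seqnum,
            rb.icode,
            rb.name,
        ):
            raise ValueError(
                f"residue identity mismatch: {ra.label()} vs {rb.label()}"
            )
    ca_a = np.array([a.pos(i, "CA") for i in range(4)])
    ca_b = np.array([b.pos(i, "CA") for i in range(4)])
    rot, trans, _ = superpose(ca_b, ca_a)

    co_a = carbonyl_direction(a)
    nh_a = amide_direction(a)
    co_b = apply_transform(carbonyl_direction(b), rot, np.zeros(3))
    nh_b = apply_transform(amide_direction(b), rot, np.zeros(3))

    omega_a = backbone_torsions(a).omega_central
    omega_b = backbone_torsions(b).omega_central
    co_angle = vector_angle(co_a, co_b)
    nh_angle = vector_angle(nh_a, nh_b)
    delta_omega = abs(wrap_angle(omega_a - omega_b))

    conf_a = peptide_conformation(omega_a, cfg)
    conf_b = peptide_conformation(omega_b, cfg)
    flip = assign_flip_code(conf_a, conf_b, co_angle, nh_angle, cfg)
    return PeptideComparison(
        co_angle=co_angle,
        nh_angle=nh_angle,
        delta_omega=delta_omega,
        omega_a=omega_a,
        omega_b=omega_b,
        flip=flip,
    )


def reverse_code(code: str) -> str:
    """Symbol-reversed code: comparing (b, a) instead of (a, b)."""
    if code == "indeterminate":
        return code
    return code[1] + code[0] + code[2]
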