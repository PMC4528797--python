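"""Per-tetrapeptide descriptors: distances, angles, torsions, chiral
volumes, carbonyl pseudo-torsions, the O bump score, a minimal 3-state
secondary structure, carbonyl–helix alignment and the Weiss–Hilgenfeld
penalty score.

Misassigned peptide planes leave characteristic fingerprints in exactly
these quantities — e.g. a compressed Cα(i−1)–C(i−1)–N(i) angle and a
shortened Cα–Cα distance for a trans peptide that should be cis, or an
elevated carbonyl-O B factor for a plane in need of a tt+ flip — so this
descriptor set is what both the explicit decision rules and the Random
Forest classifiers consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .config import RunConfig
from .conformation import backbone_torsions, infer_amide_hydrogen
from .geometry import bond_angle, chiral_volume, dihedral_angle, distance, vector_angle
from .structure import Residue, StructureModel, Tetrapeptide

__all__ = [
    "FeatureVector",
    "compute_feature_vector",
    "bump_score",
    "assign_secondary_structure",
    "carbonyl_helix_alignment",
    "wh_dtot",
    "wh_classify",
    "WH_THRESHOLD_ORIGINAL",
    "WH_THRESHOLD_REDETERMINED",
    "features_dataframe",
    "FEATURE_COLUMNS",
]

#: WH penalty-score decision thresholds: the originally published cutoff
#: and the cutoff redetermined on electron-density-validated cases.
WH_THRESHOLD_ORIGINAL = 143.10
WH_THRESHOLD_REDETERMINED = 82.256


@dataclass
class FeatureVector:
    """Descriptor set for one tetrapeptide (indices: residues 1–4, central
    peptide bond between residues 2 and 3).  Angle fields are degrees,
    distances Å, chiral volumes Å³, B factors Å²; Cβ-dependent fields are
    NaN for Gly."""

    # distances
    ca_ca: float
    cb_cb: float
    o_o_prev: float   # O1–O2
    o_o_next: float   # O2–O3
    # central-bond torsions
    omega: float
    phi2: float
    psi2: float
    phi3: float
    psi3: float
    omega_prev: float
    omega_next: float
    # bond lengths around the central bond
    len_ca2_c2: float
    len_c2_n3: float
    len_n3_ca3: float
    len_c2_o2: float
    # bond angles
    ang_o2_c2_n3: float
    ang_ca2_c2_n3: float
    ang_ca2_c2_o2: float
    ang_c2_n3_ca3: float
    tau3: float        # N3–Cα3–C3
    tau2: float        # N2–Cα2–C2
    ang_ca3_c3_n4: float
    # chiral volumes
    chiral_ca2: float
    chiral_ca3: float
    # carbonyl pseudo-torsions C–O–C–O and carbonyl–carbonyl angle
    coco_prev: float   # C1–O1–C2–O2
    coco_next: float   # C2–O2–C3–O3
    co_co_angle: float  # central C=O vs preceding C=O
    # environment
    o_bump_score: float
    helix_co_angle: float  # NaN when no helix nearby in sequence
    ss1: str
    ss2: str
    ss3: str
    ss4: str
    # B factors
    b_c2: float
    b_o2: float
    b_n3: float
    b_ca2: float
    b_ca3: float
    # context
    resolution: float
    wh_dtot: float     # NaN for X-Pro / X-Gly (method is X-Xnpg only)
    residue_class: str = ""
    label: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_COLUMNS = [f.name for f in fields(FeatureVector)]

# fixed van der Waals radii for the bump score (Å)
_DEFAULT_VDW = {"O": 1.52, "N": 1.55, "C": 1.70, "S": 1.80}


def bump_score(t: Tetrapeptide, s: StructureModel | None, cfg: RunConfig | None = None) -> float:
    """Summed van der Waals overlap of the central peptide O with
    non-bonded neighbours.

    Atoms covalently bonded or 1-3 related to O2, and the backbone of the
    two central residues, are excluded; each remaining atom within the
    search cutoff contributes max(0, r_vdw(O) + r_vdw(other) − d) Å.
    """
    cfg = cfg or RunConfig()
    radii = cfg.vdw_radii or _DEFAULT_VDW
    o2 = t.pos(1, "O")
    r_o = radii.get("O", 1.52)
    excluded = {id(a) for r in (t[1], t[2]) for a in r.atoms}
    score = 0.0
    pool = s.all_atoms() if s is not None else ((r, a) for r in t.residues for a in r.atoms)
    for _, a in pool:
        if id(a) in excluded:
            continue
        d = distance(o2, a.position)
        if d > cfg.bump_cutoff or d < 1e-6:
            continue
        overlap = r_o + radii.get(a.element.upper()[:1], 1.70) - d
        if overlap > 0:
            score += overlap
    return score


# ---------------------------------------------------------------------------
# minimal Kabsch–Sander 3-state secondary structure

_Q1Q2_F = 0.42 * 0.20 * 332.0  # kcal/mol scaling of the electrostatic model
_HB_CUTOFF = -0.5


def _ks_hbond_energy(donor: Residue, prev_c: np.ndarray | None, acceptor: Residue) -> float | None:
    """Kabsch–Sander electrostatic H-bond energy donor(N–H) → acceptor(C=O)."""
    if donor.name == "PRO" or prev_c is None:
        return None
    try:
        n = donor.pos("N")
        c = acceptor.pos("C")
        o = acceptor.pos("O")
    except KeyError:
        return None
    u = prev_c - n
    v = donor.pos("CA") - n
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    d = -(u + v)
    h = n + d / np.linalg.norm(d)
    r_on = distance(o, n)
    r_oh = distance(o, h)
    r_cn = distance(c, n)
    r_ch = distance(c, h)
    if min(r_on, r_oh, r_cn, r_ch) < 0.5:
        return None
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(s: StructureModel) -> dict[tuple[str, int, str], str]:
    """3-state secondary structure {H, E, C} per residue.

    Backbone H-bonds are scored with the Kabsch–Sander energy (bond when
    E < −0.5 kcal/mol, amide H inferred from geometry); α-helix (H) needs
    two consecutive i→i+4 turns, strand (E) an (anti)parallel bridge
    pattern; everything else, or any residue with incomplete backbone,
    is coil (C).
    """
    order: list[tuple[str, int]] = []  # (chain, index)
    residues: dict[str, list[Residue]] = {}
    for chain_id, rs in s.chains.items():
        residues[chain_id] = rs
        order.extend((chain_id, i) for i in range(len(rs)))

    def prev_c(chain_id, i):
        if i == 0:
            return None
        try:
            return residues[chain_id][i - 1].pos("C")
        except KeyError:
            return None

    # hbond[(ci, i)][(cj, j)] = True when N–H of i donates to C=O of j
    hbond: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    for ci, i in order:
        for cj, j in order:
            if ci == cj and abs(i - j) < 2:
                continue
            e = _ks_hbond_energy(residues[ci][i], prev_c(ci, i), residues[cj][j])
            if e is not None and e < _HB_CUTOFF:
                hbond.add(((ci, i), (cj, j)))

    ss: dict[tuple[str, int], str] = {key: "C" for key in order}

    # helices: two consecutive i→i+4 turns
    for ci, rs in residues.items():
        n = len(rs)
        turn = [((ci, i + 4), (ci, i)) in hbond for i in range(n - 4)]
        for i in range(len(turn) - 1):
            if turn[i] and turn[i + 1]:
                for k in range(i + 1, i + 5):
                    ss[(ci, k)] = "H"

    # bridges (strands)
    def hb(i, j):
        return (i, j) in hbond

    for ci, i in order:
        for cj, j in order:
            if ci == cj and abs(i - j) < 3:
                continue
            a, b = (ci, i), (cj, j)
            am, ap = (ci, i - 1), (ci, i + 1)
            bm, bp = (cj, j - 1), (cj, j + 1)
            parallel = (hb(am, b) and hb(b, ap)) or (hb(bm, a) and hb(a, bp))
            anti = (hb(a, b) and hb(b, a)) or (hb(am, bp) and hb(bm, ap))
            if parallel or anti:
                for key in (a, b):
                    if ss.get(key) == "C":
                        ss[key] = "E"

    return {
        (ci, residues[ci][i].seqnum, residues[ci][i].icode): code
        for (ci, i), code in ss.items()
    }


def carbonyl_helix_alignment(
    t: Tetrapeptide,
    s: StructureModel,
    ss: dict | None = None,
    cfg: RunConfig | None = None,
) -> float:
    """Angle between the central C=O and the axis of an α-helix nearby in
    sequence (within ±helix_window residues); NaN when there is none.

    The helix axis is the least-squares line through the centroids of
    consecutive 4-Cα windows of the helix.
    """
    cfg = cfg or RunConfig()
    if ss is None:
        ss = assign_secondary_structure(s)
    chain_id = t[1].chain_id
    rs = s.chains.get(chain_id, [])
    idx2 = next(
        (i for i, r in enumerate(rs) if (r.seqnum, r.icode) == (t[1].seqnum, t[1].icode)),
        None,
    )
    if idx2 is None:
        return math.nan
    codes = [ss.get((chain_id, r.seqnum, r.icode), "C") for r in rs]
    lo = max(0, idx2 - cfg.helix_window)
    hi = min(len(rs), idx2 + cfg.helix_window + 1)
    # longest helix run intersecting the window
    best: tuple[int, int] | None = None
    run_start = None
    for i in range(len(rs) + 1):
        if i < len(rs) and codes[i] == "H":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if i - run_start >= 4 and not (i <= lo or run_start >= hi):
                    if best is None or i - run_start > best[1] - best[0]:
                        best = (run_start, i)
                run_start = None
    if best is None:
        return math.nan
    try:
        cas = np.array([rs[i].pos("CA") for i in range(best[0], best[1])])
    except KeyError:
        return math.nan
    centroids = np.array([cas[i : i + 4].mean(axis=0) for i in range(len(cas) - 3)])
    if len(centroids) < 2:
        axis = cas[-1] - cas[0]
    else:
        c0 = centroids.mean(axis=0)
        _, _, vt = np.linalg.svd(centroids - c0)
        axis = vt[0]
        if np.dot(axis, centroids[-1] - centroids[0]) < 0:
            axis = -axis
    co = t.pos(1, "O") - t.pos(1, "C")
    return vector_angle(co, axis)


# ---------------------------------------------------------------------------
# Weiss–Hilgenfeld penalty score (surrogate form)

def _ideal_trans_ca_ca() -> float:
    """Cα–Cα distance implied by the ideal trans parameters (exact)."""
    from .geometry import place_atom as _place

    a = np.zeros(3)
    b = np.array([1.525, 0.0, 0.0])
    th = math.radians(116.2)
    c = b + 1.329 * np.array([-math.cos(th), math.sin(th), 0.0])
    d = _place(a, b, c, 1.458, 121.7, 180.0)
    return float(np.linalg.norm(d - a))


# reference geometry and deviation scales for the strain variables of a
# trans X-Xnpg peptide: (reference, scale).  The reference values are the
# ideal-build geometry (Engh–Huber-style); scales are typical refined
# spreads.  The score is zero at the reference and grows quadratically.
_WH_TERMS = {
    "phi3": (-120.0, 30.0),
    "ang_o2_c2_n3": (123.0, 2.0),
    "ang_ca2_c2_n3": (116.2, 2.0),
    "ang_ca2_c2_o2": (120.8, 2.0),
    "ang_c2_n3_ca3": (121.7, 2.0),
    "ca_ca": (_ideal_trans_ca_ca(), 0.05),
}


def wh_dtot(t: Tetrapeptide) -> float:
    """Weiss–Hilgenfeld-style penalty score D_tot for a trans X-Xnpg
    peptide: sum of squared standardized deviations of the strain
    variables (φ_i, the three angles at C2, the C2–N3–Cα3 angle and the
    Cα–Cα distance) from their trans reference values.

    Zero at the reference geometry, strictly positive off it; large
    values flag trans-modelled peptides that are really cis (tc−
    candidates).  Defined for X-Xnpg tetrapeptides only.
    """
    from .structure import residue_class

    if residue_class(t) != "X-Xnpg":
        raise ValueError("WH undefined for this class (X-Xnpg only)")
    tor = backbone_torsions(t)
    values = {
        "phi3": tor.phi3,
        "ang_o2_c2_n3": bond_angle(t.pos(1, "O"), t.pos(1, "C"), t.pos(2, "N")),
        "ang_ca2_c2_n3": bond_angle(t.pos(1, "CA"), t.pos(1, "C"), t.pos(2, "N")),
        "ang_ca2_c2_o2": bond_angle(t.pos(1, "CA"), t.pos(1, "C"), t.pos(1, "O")),
        "ang_c2_n3_ca3": bond_angle(t.pos(1, "C"), t.pos(2, "N"), t.pos(2, "CA")),
        "ca_ca": distance(t.pos(1, "CA"), t.pos(2, "CA")),
    }
    score = 0.0
    for key, (ref, scale) in _WH_TERMS.items():
        dev = values[key] - ref
        if key == "phi3":
            dev = (dev + 180.0) % 360.0 - 180.0
        score += (dev / scale) ** 2
    return score


def wh_classify(score: float, threshold: float = WH_THRESHOLD_REDETERMINED) -> str:
    """'flip' (tc− candidate) when the penalty score exceeds the
    threshold, else 'no-flip'."""
    return "flip" if score > threshold else "no-flip"


# ---------------------------------------------------------------------------


def compute_feature_vector(
    t: Tetrapeptide,
    s: StructureModel | None = None,
    cfg: RunConfig | None = None,
    ss: dict | None = None,
) -> FeatureVector:
    """All descriptors for one tetrapeptide within its source model."""
    from .structure import residue_class
    from .synthetic import as_structure  # lightweight wrapper, no cycle at call time

    cfg = cfg or RunConfig()
    if s is None:
        s = as_structure(t)
    if ss is None:
        ss = assign_secondary_structure(s)
    tor = backbone_torsions(t)
    p = t.pos

    def cb_cb():
        try:
            return distance(p(1, "CB"), p(2, "CB"))
        except KeyError:
            return math.nan

    def chiral(i):
        try:
            return chiral_volume(p(i, "CA"), p(i, "N"), p(i, "C"), p(i, "CB"))
        except KeyError:
            return math.nan

    ss_codes = [
        ss.get((r.chain_id, r.seqnum, r.icode), "C") for r in t.residues
    ]
    rc = residue_class(t)
    wh = math.nan
    if rc == "X-Xnpg":
        wh = wh_dtot(t)

    return FeatureVector(
        ca_ca=distance(p(1, "CA"), p(2, "CA")),
        cb_cb=cb_cb(),
        o_o_prev=distance(p(0, "O"), p(1, "O")),
        o_o_next=distance(p(1, "O"), p(2, "O")),
        omega=tor.omega_central,
        phi2=tor.phi2,
        psi2=tor.psi2,
        phi3=tor.phi3,
        psi3=tor.psi3,
        omega_prev=tor.omega_prev,
        omega_next=tor.omega_next,
        len_ca2_c2=distance(p(1, "CA"), p(1, "C")),
        len_c2_n3=distance(p(1, "C"), p(2, "N")),
        len_n3_ca3=distance(p(2, "N"), p(2, "CA")),
        len_c2_o2=distance(p(1, "C"), p(1, "O")),
        ang_o2_c2_n3=bond_angle(p(1, "O"), p(1, "C"), p(2, "N")),
        ang_ca2_c2_n3=bond_angle(p(1, "CA"), p(1, "C"), p(2, "N")),
        ang_ca2_c2_o2=bond_angle(p(1, "CA"), p(1, "C"), p(1, "O")),
        ang_c2_n3_ca3=bond_angle(p(1, "C"), p(2, "N"), p(2, "CA")),
        tau3=bond_angle(p(2, "N"), p(2, "CA"), p(2, "C")),
        tau2=bond_angle(p(1, "N"), p(1, "CA"), p(1, "C")),
        ang_ca3_c3_n4=bond_angle(p(2, "CA"), p(2, "C"), p(3, "N")),
        chiral_ca2=chiral(1),
        chiral_ca3=chiral(2),
        coco_prev=dihedral_angle(p(0, "C"), p(0, "O"), p(1, "C"), p(1, "O")),
        coco_next=dihedral_angle(p(1, "C"), p(1, "O"), p(2, "C"), p(2, "O")),
        co_co_angle=vector_angle(p(1, "O") - p(1, "C"), p(0, "O") - p(0, "C")),
        o_bump_score=bump_score(t, s, cfg),
        helix_co_angle=carbonyl_helix_alignment(t, s, ss, cfg),
        ss1=ss_codes[0],
        ss2=ss_codes[1],
        ss3=ss_codes[2],
        ss4=ss_codes[3],
        b_c2=t[1].atom("C").b_factor,
        b_o2=t[1].atom("O").b_factor,
        b_n3=t[2].atom("N").b_factor,
        b_ca2=t[1].atom("CA").b_factor,
        b_ca3=t[2].atom("CA").b_factor,
        resolution=t.resolution if t.resolution is not None else math.nan,
        wh_dtot=wh,
        residue_class=rc,
    )


def features_dataframe(examples, cfg: RunConfig | None = None):
    """Feature table (pandas DataFrame) for a list of LabelledExamples or
    Tetrapeptides; labelled rows carry their flip label."""
    import pandas as pd

    rows = []
    for ex in examples:
        t = getattr(ex, "tetrapeptide", ex)
        fv = compute_feature_vector(t, cfg=cfg)
        d = fv.to_dict()
        if hasattr(ex, "tetrapeptide"):  # LabelledExample
            d["label"] = ex.label
            d["residue_class"] = ex.residue_class
        rows.append(d)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_dssp(path) -> dict[tuple[str, int, str], str]:
    """Read a standard DSSP output file into the 3-state per-residue map
    used by this package (helix classes → H, strand/bridge → E, else C)."""
    mapping = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
    out: dict[tuple[str, int, str], str] = {}
    started = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                started = True
                continue
            if not started or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            try:
                seqnum = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip()
            chain = line[11].strip()
            code = line[16].strip()
            out[(chain, seqnum, icode)] = mapping.get(code, "C")
    return out
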