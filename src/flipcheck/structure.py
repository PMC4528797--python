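"""Coordinate-file handling and tetrapeptide extraction.

Reads PDB/mmCIF models (via gemmi), applies entry-level selection criteria
(X-ray, resolution, chain length) and residue-level criteria (canonical
type, complete backbone, full occupancy, positive B, no alternate
locations, no chain breaks, no disulfide involvement, no close foreign
contact to the central carbonyl O), and yields the four-residue windows
that all downstream analysis operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import distance

log = logging.getLogger(__name__)

CANONICAL = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    b_factor: float = 20.0
    occupancy: float = 1.0
    alt_loc: str = ""


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def pos(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"missing atom {name} in {self.label()}")
        return a.position

    def has(self, name: str) -> bool:
        return self.atom(name) is not None

    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seqnum}{self.icode}".strip()

    @property
    def is_amino_acid(self) -> bool:
        return self.has("CA") and self.has("N")


@dataclass
class StructureModel:
    entry_id: str
    method: str | None
    resolution: float | None
    chains: dict[str, list[Residue]]
    hetero: list[AtomRecord] = field(default_factory=list)

    def all_atoms(self):
        for residues in self.chains.values():
            for r in residues:
                for a in r.atoms:
                    yield r, a
        for a in self.hetero:
            yield None, a


@dataclass
class Tetrapeptide:
    """Four consecutive residues; the central peptide bond joins residues
    2 and 3 (indices 1 and 2), i.e. residues i−1 and i of the bond."""

    residues: tuple[Residue, Residue, Residue, Residue]
    entry_id: str = ""
    resolution: float | None = None

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def pos(self, i: int, name: str) -> np.ndarray:
        return self.residues[i].pos(name)

    def label(self) -> str:
        r2, r3 = self.residues[1], self.residues[2]
        return f"{r2.chain_id}:{r2.name}{r2.seqnum}{r2.icode}-{r3.name}{r3.seqnum}{r3.icode}".strip()


def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    method = None
    try:
        if st.get_info("_exptl.method"):
            method = st.get_info("_exptl.method")
    except Exception:
        method = None
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    if len(st) == 0:
        raise ValueError(f"could not parse {path}: no coordinate model found")
    chains: dict[str, list[Residue]] = {}
    hetero: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            recs = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    b_factor=float(a.b_iso),
                    occupancy=float(a.occ),
                    alt_loc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            r = Residue(
                chain_id=chain.name,
                seqnum=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name=res.name.upper(),
                atoms=recs,
            )
            if r.name in CANONICAL or (r.has("CA") and r.has("N") and r.has("C")):
                residues.append(r)
            else:
                hetero.extend(recs)
        if residues:
            chains[chain.name] = residues
    return StructureModel(
        entry_id=st.name or path.stem,
        method=method,
        resolution=resolution,
        chains=chains,
        hetero=hetero,
    )


def entry_passes_filters(s: StructureModel, cfg=None) -> tuple[bool, list[str]]:
    """Entry-level selection: X-ray method, resolution ≤ max_resolution
    (default 3.5 Å), and at least one chain of ≥ 25 amino acids.

    Returns (accept, reasons); *reasons* lists every failed criterion.
    """
    from .config import RunConfig

    cfg = cfg or RunConfig()
    reasons = []
    if s.method is not None:
        if "X-RAY" not in s.method.upper():
            reasons.append("method")
    elif not cfg.allow_unknown_method:
        reasons.append("method")
    if s.resolution is not None:
        if s.resolution > cfg.max_resolution:
            reasons.append("resolution")
    elif not cfg.allow_unknown_method:
        reasons.append("resolution")
    if not any(
        sum(1 for r in residues if r.name in CANONICAL) >= cfg.min_chain_length
        for residues in s.chains.values()
    ):
        reasons.append("composition")
    return (not reasons), reasons


def _residue_ok(r: Residue, reasons: list[str]) -> bool:
    ok = True
    if r.name not in CANONICAL:
        reasons.append(f"{r.label()}: non-canonical")
        ok = False
        return ok
    needed = list(BACKBONE)
    if r.name != "GLY":
        needed.append("CB")
    for name in needed:
        a = r.atom(name)
        if a is None:
            reasons.append(f"{r.label()}: missing {name}")
            ok = False
            continue
        if a.alt_loc:
            reasons.append(f"{r.label()}: altloc on {name}")
            ok = False
        if a.occupancy < 1.0:
            reasons.append(f"{r.label()}: occupancy<1 on {name}")
            ok = False
        if not (a.b_factor > 0):
            reasons.append(f"{r.label()}: B<=0 on {name}")
            ok = False
    return ok


def _chain_breaks(residues: list[Residue], break_distance: float) -> set[int]:
    """Indices i such that a break lies between residues i and i+1."""
    breaks = set()
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        gap = b.seqnum - a.seqnum
        if gap > 1 or (gap not in (0, 1)):
            if not (gap == 0 and b.icode != a.icode):
                breaks.add(i)
                continue
        try:
            if distance(a.pos("C"), b.pos("N")) > break_distance:
                breaks.add(i)
        except KeyError:
            breaks.add(i)
    return breaks


def _disulfide_cys(s: StructureModel) -> set[tuple[str, int, str]]:
    sgs = []
    for residues in s.chains.values():
        for r in residues:
            if r.name == "CYS" and r.has("SG"):
                sgs.append(r)
    bad = set()
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if distance(sgs[i].pos("SG"), sgs[j].pos("SG")) < 2.5:
                bad.add((sgs[i].chain_id, sgs[i].seqnum, sgs[i].icode))
                bad.add((sgs[j].chain_id, sgs[j].seqnum, sgs[j].icode))
    return bad


def extract_tetrapeptides(s: StructureModel, cfg=None) -> list[Tetrapeptide]:
    """All four-residue windows passing the residue selection criteria.

    A window is kept when each residue is canonical, complete (backbone +
    Cβ for non-Gly, occupancy 1, B > 0, no altlocs), not a chain terminus,
    not adjacent to a chain break, not a disulfide-bonded Cys, and no atom
    outside the window's own chain lies within 2.5 Å of the central
    peptide O.
    """
    from .config import RunConfig

    cfg = cfg or RunConfig()
    out: list[Tetrapeptide] = []
    reject_reasons: list[str] = []
    ss_bad = _disulfide_cys(s)

    # foreign-atom lookup for the O-contact check
    foreign: dict[str, list[np.ndarray]] = {}
    for chain_id in s.chains:
        pts = [a.position for a in s.hetero]
        for other_id, residues in s.chains.items():
            if other_id == chain_id:
                continue
            pts.extend(a.position for r in residues for a in r.atoms)
        foreign[chain_id] = pts

    for chain_id, residues in s.chains.items():
        n = len(residues)
        if n < 4:
            continue
        breaks = _chain_breaks(residues, cfg.break_distance)
        usable = np.ones(n, dtype=bool)
        usable[0] = usable[-1] = False  # termini
        for i in breaks:  # residues flanking a break count as termini
            usable[i] = usable[i + 1] = False
        for i, r in enumerate(residues):
            if not usable[i]:
                continue
            rs: list[str] = []
            if not _residue_ok(r, rs):
                usable[i] = False
                reject_reasons.extend(rs)
            if (r.chain_id, r.seqnum, r.icode) in ss_bad:
                usable[i] = False
                reject_reasons.append(f"{r.label()}: disulfide bond")
        for start in range(n - 3):
            idx = range(start, start + 4)
            if not all(usable[i] for i in idx):
                continue
            if any(i < n - 1 and i in breaks for i in idx):
                continue
            window = tuple(residues[i] for i in idx)
            o2 = window[1].pos("O")
            if any(distance(o2, p) < cfg.o_contact_distance for p in foreign[chain_id]):
                reject_reasons.append(
                    f"{window[1].label()}: foreign atom within "
                    f"{cfg.o_contact_distance} Å of central O"
                )
                continue
            out.append(
                Tetrapeptide(residues=window, entry_id=s.entry_id, resolution=s.resolution)
            )
    for msg in reject_reasons:
        log.info("rejected: %s", msg)
    return out


def residue_class(t: Tetrapeptide) -> str:
    """Residue class keyed on the residue after the central bond:
    'X-Pro', 'X-Gly' or 'X-Xnpg'."""
    name = t[2].name
    if name == "PRO":
        return "X-Pro"
    if name == "GLY":
        return "X-Gly"
    return "X-Xnpg"


def write_pdb(s: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file."""
    st = to_gemmi(s)
    st.write_pdb(str(path))


def write_mmcif(s: StructureModel, path) -> None:
    st = to_gemmi(s)
    st.make_mmcif_document().write_file(str(path))


def to_gemmi(s: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.entry_id or "XXXX"
    if s.resolution:
        st.resolution = s.resolution
    st.raw_remarks = []
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element or a.name[0])
                atom.pos = gemmi.Position(*a.position)
                atom.b_iso = a.b_factor
                atom.occ = a.occupancy
                if a.alt_loc:
                    atom.altloc = a.alt_loc
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st
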