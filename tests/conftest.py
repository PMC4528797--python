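import numpy as np
import pytest

from flipcheck.config import RunConfig
from flipcheck.synthetic import (
    BuildSpec,
    build_chain,
    build_tetrapeptide,
    chain_structure,
)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def ideal_trans():
    """Ideal trans tetrapeptide (Ala-Ser-Leu-Ala, ω = 180)."""
    return build_tetrapeptide(BuildSpec())


@pytest.fixture
def ideal_cis():
    return build_tetrapeptide(BuildSpec(omega=0.0))


@pytest.fixture
def ideal_cis_pro():
    return build_tetrapeptide(BuildSpec(residues=("ALA", "SER", "PRO", "ALA"), omega=0.0))


@pytest.fixture
def ideal_trans_pro():
    return build_tetrapeptide(BuildSpec(residues=("ALA", "SER", "PRO", "ALA")))


@pytest.fixture
def helix_structure():
    """12-residue ideal α-helix (φ=−57, ψ=−47)."""
    return chain_structure(build_chain(["ALA"] * 12))


@pytest.fixture
def sheet_structure():
    """Two ideal extended strands placed antiparallel so that the central
    residues form a Kabsch–Sander bridge."""
    a = build_chain(["ALA"] * 8, phi=-139, psi=135, chain_id="A")
    b = build_chain(["ALA"] * 8, phi=-139, psi=135, chain_id="B")
    flip = np.diag([1.0, -1.0, -1.0])
    shift = np.array([-3.5, 5.0, 0.0])
    for r in b:
        for at in r.atoms:
            at.position = flip @ at.position + shift
    return chain_structure([a, b])


def random_rigid_motion(rng):
    """Random rotation matrix (via QR) and translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return q, t


def transform_tetrapeptide(t, rot, trans):
    import copy

    out = copy.deepcopy(t)
    for res in out.residues:
        for a in res.atoms:
            a.position = rot @ a.position + trans
    return out
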