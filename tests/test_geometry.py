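"""Geometry primitives: exact values, sign conventions, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flipcheck.geometry import (
    bond_angle,
    chiral_volume,
    dihedral_angle,
    distance,
    place_atom,
    superpose,
    vector_angle,
    wrap_angle,
)

from conftest import random_rigid_motion


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
    ],
)
def test_distance(a, b, expected):
    assert distance(a, b) == pytest.approx(expected)
    assert distance(b, a) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a,v,c,expected",
    [
        ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
    ],
)
def test_bond_angle(a, v, c, expected):
    assert bond_angle(a, v, c) == pytest.approx(expected)
    assert bond_angle(c, v, a) == pytest.approx(expected)


def test_bond_angle_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


@pytest.mark.parametrize(
    "p4,expected",
    [((-1, 1, 0), 180.0), ((1, 1, 0), 0.0), ((0, 1, 1), -90.0)],
)
def test_dihedral_convention(p4, expected):
    got = dihedral_angle((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
    assert got == pytest.approx(expected)


def test_dihedral_reversal_invariance():
    rng = np.random.default_rng(1)
    for _ in range(50):
        pts = rng.normal(size=(4, 3)) * 3
        try:
            fwd = dihedral_angle(*pts)
        except ValueError:
            continue
        rev = dihedral_angle(*pts[::-1])
        assert fwd == pytest.approx(rev, abs=1e-9)


def test_dihedral_collinear_error():
    with pytest.raises(ValueError, match="torsion"):
        dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_dihedral_against_rotation_oracle():
    """Independent oracle: place p4 by explicit rotation about the p2→p3
    axis starting from the eclipsed position; the measured torsion must
    equal the applied rotation to 1e−6 degrees (1000 random cases)."""
    from flipcheck.geometry import rotation_about_axis

    rng = np.random.default_rng(42)
    n = 0
    while n < 1000:
        p1, p2, p3 = rng.normal(scale=3.0, size=(3, 3))
        axis = p3 - p2
        if np.linalg.norm(axis) < 0.3:
            continue
        # eclipsed reference: p4 in the p1-p2-p3 plane, on p1's side
        u = p1 - p2
        perp = u - (u @ axis) / (axis @ axis) * axis
        if np.linalg.norm(perp) < 0.3:
            continue
        angle = float(rng.uniform(-179.9, 179.9))
        p4_0 = p3 + perp / np.linalg.norm(perp)
        p4 = rotation_about_axis(p3, axis, angle)(p4_0)
        got = dihedral_angle(p1, p2, p3, p4)
        # rotating the far atom by +θ about the p2→p3 axis from the
        # eclipsed position gives torsion +θ under the IUPAC convention
        assert abs(wrap_angle(got - angle)) < 1e-6
        n += 1


def test_dihedral_oracle_sign():
    """The rotation oracle with a fixed handedness pins the sign."""
    from flipcheck.geometry import rotation_about_axis

    p1, p2, p3 = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])
    p4_0 = p3 + np.array([1.0, 0, 0])  # eclipsed w.r.t. p1
    for angle in (-120.0, -45.0, 30.0, 150.0):
        p4 = rotation_about_axis(p3, p3 - p2, angle)(p4_0)
        assert dihedral_angle(p1, p2, p3, p4) == pytest.approx(angle, abs=1e-9)


@pytest.mark.parametrize(
    "order,expected",
    [(("a", "b", "c"), 1.0), (("a", "c", "b"), -1.0)],
)
def test_chiral_volume_parity(order, expected):
    pts = {"a": (1, 0, 0), "b": (0, 1, 0), "c": (0, 0, 1)}
    got = chiral_volume((0, 0, 0), *(pts[k] for k in order))
    assert got == pytest.approx(expected)


def test_chiral_volume_ideal_l_residue():
    """Cα of an ideal L-residue: chiral volume of (N, C, Cβ) about Cα is
    positive, near +2.5 Å³ (hand-constructed tetrahedral oracle)."""
    # N along +x; C in the xy-plane at the tetrahedral backbone angle
    # 111° from N; Cβ placed at 110.5° with the L-configuration improper
    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    t = math.radians(111.0)
    c = 1.525 * np.array([math.cos(t), math.sin(t), 0.0])
    cb = place_atom(c, n, ca, 1.530, 110.5, -122.6)
    v = chiral_volume(ca, n, c, cb)
    assert 2.3 < v < 2.7


def test_rigid_motion_invariance():
    rng = np.random.default_rng(7)
    pts = rng.normal(scale=3.0, size=(4, 3))
    d0 = distance(pts[0], pts[1])
    a0 = bond_angle(pts[0], pts[1], pts[2])
    t0 = dihedral_angle(*pts)
    c0 = chiral_volume(*pts)
    for _ in range(20):
        rot, tr = random_rigid_motion(rng)
        moved = pts @ rot.T + tr
        assert distance(moved[0], moved[1]) == pytest.approx(d0, abs=1e-9)
        assert bond_angle(moved[0], moved[1], moved[2]) == pytest.approx(a0, abs=1e-9)
        assert dihedral_angle(*moved) == pytest.approx(t0, abs=1e-8)
        assert chiral_volume(*moved) == pytest.approx(c0, abs=1e-9)


def test_chiral_volume_reflection_antisymmetry():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(4, 3))
    mirrored = pts * np.array([1, 1, -1])
    assert chiral_volume(*mirrored) == pytest.approx(-chiral_volume(*pts))


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rotation_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        theta = math.radians(90)
        rz = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        rot, trans, rmsd = superpose(pts, pts @ rz.T)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, rz, atol=1e-9)

    def test_noisy_rmsd_matches_expectation(self):
        """Two noisy copies of the same points: RMSD is close to the
        Monte-Carlo expectation sqrt(2)·σ·sqrt(3)·(1−k/n correction);
        assert the generous 3σ band the construction guarantees."""
        rng = np.random.default_rng(5)
        base = rng.normal(scale=5.0, size=(100, 3))
        sigma = 0.1
        a = base + rng.normal(scale=sigma, size=base.shape)
        b = base + rng.normal(scale=sigma, size=base.shape)
        _, _, rmsd = superpose(a, b)
        expected = sigma * math.sqrt(2 * 3)  # both copies noisy, 3 dims
        assert abs(rmsd - expected) < 3 * sigma / math.sqrt(2)

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([1, 1, -1])
        rot, _, rmsd = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_degenerate_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.mark.parametrize(
    "u,v,expected",
    [((1, 0, 0), (1, 0, 0), 0.0), ((1, 0, 0), (-1, 0, 0), 180.0), ((1, 0, 0), (0, 1, 0), 90.0)],
)
def test_vector_angle(u, v, expected):
    assert vector_angle(u, v) == pytest.approx(expected)
    assert vector_angle(v, u) == pytest.approx(expected)


def test_vector_angle_zero_vector():
    with pytest.raises(ValueError):
        vector_angle((0, 0, 0), (1, 0, 0))


@given(st.floats(-1e4, 1e4))
@settings(deadline=None, derandomize=True)
def test_wrap_angle_range(x):
    w = wrap_angle(x)
    assert -180.0 < w <= 180.0
    assert abs((x - w) % 360.0) < 1e-6 or abs((x - w) % 360.0 - 360.0) < 1e-6


def test_place_atom_roundtrip():
    rng = np.random.default_rng(9)
    a, b, c = rng.normal(scale=3, size=(3, 3))
    for tor in (-150.0, -60.0, 0.0, 75.0, 180.0):
        d = place_atom(a, b, c, 1.5, 109.5, tor)
        assert distance(c, d) == pytest.approx(1.5)
        assert bond_angle(b, c, d) == pytest.approx(109.5)
        assert dihedral_angle(a, b, c, d) == pytest.approx(tor, abs=1e-9)
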