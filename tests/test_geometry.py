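import numpy as np
import pytest

import coilkit as ck
from coilkit.errors import (AxisError, CorrespondenceError,
                            EmptyAggregateError, SelectionError)
from coilkit.geometry import (SpacingProfile, SpacingRecord, Transform,
                              heptad_spacing, helix_axis, interaxis_angle,
                              kabsch, region_rmsd, regular_region_mean,
                              spacing_profile)
from coilkit.register import Heptad, enumerate_heptads
from coilkit.structure import selection
from coilkit.synthetic import CrickParams, build_crick_dimer
from tests.conftest import brute_force_min_rmsd, random_rigid, straight_dimer


# ---------------------------------------------------------------------------
# kabsch


def test_kabsch_identity():
    P = np.random.default_rng(0).normal(size=(10, 3))
    t, rmsd = kabsch(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(15, 3))
    R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    Q = P @ R.T + np.array([3.0, -2.0, 7.0])
    _, rmsd = kabsch(P, Q)
    assert rmsd < 1e-6


def test_kabsch_matches_brute_force_rotation_search():
    rng = np.random.default_rng(7)
    for i in range(20):
        P = rng.normal(size=(10, 3)) * 3.0
        Q = rng.normal(size=(10, 3)) * 3.0
        _, rmsd = kabsch(P, Q)
        brute = brute_force_min_rmsd(P, Q, seed=i)
        assert rmsd <= brute + 1e-9          # kabsch is the true optimum
        assert abs(rmsd - brute) < 1e-3


def test_kabsch_not_worse_than_unsuperposed():
    rng = np.random.default_rng(3)
    for _ in range(10):
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3)) + rng.normal(size=3)
        _, rmsd = kabsch(P, Q)
        raw = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
        assert rmsd <= raw + 1e-12


def test_kabsch_errors():
    with pytest.raises(CorrespondenceError):
        kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
    with pytest.raises(CorrespondenceError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_transform_rejects_improper_rotation():
    with pytest.raises(ValueError):
        Transform(rotation=np.diag([1.0, 1.0, -1.0]), translation=np.zeros(3))


# ---------------------------------------------------------------------------
# spacing


def test_ideal_coil_spacing_symmetry(ideal_dimer):
    model, assign = ideal_dimer
    # a and d straddle the interface slightly asymmetrically even in the
    # ideal construction; the residual |da - da'| stays well under 0.3 A
    for h in enumerate_heptads(assign)[2:-2]:
        rec = heptad_spacing(model, ("A", "B"), h)
        assert abs(rec.da - rec.da_prime) < 0.3


def test_spacing_profile_flat_on_ideal_dimer(ideal_dimer):
    model, assign = ideal_dimer
    profile = spacing_profile(model, ("A", "B"), enumerate_heptads(assign))
    means = [m for m in profile.means() if m is not None]
    assert np.std(means) < 0.1


def test_spacing_missing_residue_marks_record(ideal_dimer):
    model, _ = ideal_dimer
    h = Heptad(a=900, a_prime=907, d=903)  # absent residues
    rec = heptad_spacing(model, ("A", "B"), h)
    assert rec.da is None and rec.da_prime is None and rec.mean is None


def test_empty_heptad_list_gives_empty_profile(ideal_dimer):
    model, _ = ideal_dimer
    assert spacing_profile(model, ("A", "B"), []).records == []


def test_spacing_mean_increases_with_superhelical_radius():
    means = []
    for r0 in (4.0, 4.5, 4.9, 5.5, 6.0):
        model, assign = build_crick_dimer(CrickParams(n_res=35, R0=r0))
        profile = spacing_profile(model, ("A", "B"), enumerate_heptads(assign))
        means.append(np.mean([m for m in profile.means() if m is not None]))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_regular_region_mean_arithmetic():
    def rec(a, value):
        h = Heptad(a=a, a_prime=a + 7, d=a + 3)
        return SpacingRecord(heptad=h, da=value, da_prime=value)

    p = SpacingProfile(records=[rec(1, 7.0), rec(8, 8.0), rec(15, 9.0)],
                       chain_pair=("A", "B"))
    assert regular_region_mean(p) == pytest.approx(8.0)
    # exclusion by d position: drop the middle heptad (d=11)
    assert regular_region_mean(p, exclude=(10, 12)) == pytest.approx(8.0)
    assert regular_region_mean(p, exclude=(4, 11)) == pytest.approx(9.0)
    with pytest.raises(EmptyAggregateError):
        regular_region_mean(p, exclude=(0, 100))


def test_profile_tsv_fixed_format():
    h = Heptad(a=23, a_prime=30, d=26)
    p = SpacingProfile(records=[SpacingRecord(heptad=h, da=7.5, da_prime=None)],
                       chain_pair=("A", "B"), structure_label="demo")
    assert p.to_tsv() == (
        "a\ta_prime\td\tda\tda_prime\tmean\tstructure_label\n"
        "23\t30\t26\t7.50\tNA\tNA\tdemo\n")


# ---------------------------------------------------------------------------
# region RMSD


def test_region_rmsd_self_is_zero(ideal_dimer):
    model, _ = ideal_dimer
    rmsd, cmap = region_rmsd(model, model,
                             selection(chains=["A", "B"], atom_class="calpha"))
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert cmap in ({"A": "A", "B": "B"}, {"A": "B", "B": "A"})


def test_region_rmsd_auto_is_min_over_pairings(ideal_dimer):
    model, _ = ideal_dimer
    rng = np.random.default_rng(9)
    R, t = random_rigid(rng)
    other = model.transformed(R, t)
    sel = selection(chains=["A", "B"], ranges=[(5, 60)], atom_class="calpha")
    auto, _ = region_rmsd(model, other, sel, chain_map="auto")
    explicit = [region_rmsd(model, other, sel, chain_map=m)[0]
                for m in ({"A": "A", "B": "B"}, {"A": "B", "B": "A"})]
    assert auto == pytest.approx(min(explicit), abs=1e-9)


def test_region_rmsd_insufficient_overlap(ideal_dimer):
    model, _ = ideal_dimer
    with pytest.raises(CorrespondenceError):
        region_rmsd(model, model, selection(chains=["A", "B"], ranges=[(800, 900)]))


# ---------------------------------------------------------------------------
# helix axes


def test_helix_axis_of_straight_helix_matches_construction():
    s = straight_dimer(n_res=21)
    ax = helix_axis(s, "A", (1, 21))
    angle = np.degrees(np.arccos(abs(ax.direction @ np.array([0.0, 0.0, 1.0]))))
    assert angle < 1.0
    assert ax.direction[2] > 0  # oriented N -> C (+z)


def test_helix_axis_orientation_flips_with_residue_order():
    s = straight_dimer(n_res=21)
    flipped = straight_dimer(n_res=21)
    # reverse the coordinates along the chain (renumber to keep order valid)
    coords = [r.atoms[0].coord.copy() for r in s.chains["A"]][::-1]
    for res, c in zip(flipped.chains["A"], coords):
        res.atoms[0].coord[:] = c
    ax1 = helix_axis(s, "A", (1, 21))
    ax2 = helix_axis(flipped, "A", (1, 21))
    assert np.dot(ax1.direction, ax2.direction) < -0.99


def test_helix_axis_needs_enough_residues():
    s = straight_dimer(n_res=21)
    with pytest.raises(AxisError):
        helix_axis(s, "A", (1, 5))


def test_interaxis_angle_basics():
    from coilkit.geometry import HelixAxis
    z = HelixAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                  residue_range=(1, 10))
    x = HelixAxis(point=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
                  residue_range=(1, 10))
    assert interaxis_angle(z, z) == pytest.approx(0.0)
    assert interaxis_angle(z, x) == pytest.approx(90.0)
    tilted = HelixAxis(point=np.zeros(3),
                       direction=np.array([np.sin(np.radians(30)), 0.0,
                                           np.cos(np.radians(30))]),
                       residue_range=(1, 10))
    assert interaxis_angle(z, tilted) == pytest.approx(30.0, abs=1e-6)
    # oriented variant distinguishes antiparallel
    anti = HelixAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, -1.0]),
                     residue_range=(1, 10))
    assert interaxis_angle(z, anti) == pytest.approx(0.0)
    assert interaxis_angle(z, anti, oriented=True) == pytest.approx(180.0)


# ---------------------------------------------------------------------------
# cross-chain distances


def test_cross_chain_distance_on_constructed_dimer():
    s = straight_dimer(separation=8.0)
    assert ck.cross_chain_ca_distance(s, 5, ("A", "B")) == pytest.approx(8.0)
    assert ck.cross_chain_ca_distance(s, 5, ("A", "A")) == 0.0
    with pytest.raises(SelectionError):
        ck.cross_chain_ca_distance(s, 999, ("A", "B"))


# ---------------------------------------------------------------------------
# rigid invariance of everything geometric


def test_geometry_invariant_under_global_rigid_motion(ideal_dimer):
    model, assign = ideal_dimer
    heptads = enumerate_heptads(assign)[:6]
    rng = np.random.default_rng(17)
    R, t = random_rigid(rng)
    moved = model.transformed(R, t)

    p1 = spacing_profile(model, ("A", "B"), heptads)
    p2 = spacing_profile(moved, ("A", "B"), heptads)
    np.testing.assert_allclose(p1.means(), p2.means(), atol=1e-6)

    a1 = helix_axis(model, "A", (5, 30))
    a1m = helix_axis(moved, "A", (5, 30))
    np.testing.assert_allclose(a1m.direction, R @ a1.direction, atol=1e-6)

    d1 = ck.cross_chain_ca_distance(model, 10, ("A", "B"))
    d2 = ck.cross_chain_ca_distance(moved, 10, ("A", "B"))
    assert d2 == pytest.approx(d1, abs=1e-6)
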