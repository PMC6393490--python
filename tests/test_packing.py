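import numpy as np
import pytest

from coilkit.errors import EmptyAggregateError
from coilkit.geometry import SpacingProfile, SpacingRecord, spacing_profile
from coilkit.packing import (find_knobs_into_holes, find_polar_core_contacts,
                             find_salt_bridges, flag_underwound,
                             underwound_regions)
from coilkit.register import Heptad, enumerate_heptads, parse_register
from tests.conftest import make_structure


def core_positions(assign, chain_ids=("A", "B")):
    core = [n for n, letter in assign.letters.items() if letter in ("a", "d")]
    return [(c, n) for c in chain_ids for n in core]


def test_knob_fraction_high_on_ideal_dimer(ideal_dimer):
    model, assign = ideal_dimer
    knobs = find_knobs_into_holes(model, ("A", "B"))
    knob_keys = {(k.knob[0], k.knob[1]) for k in knobs}
    core = core_positions(assign)
    fraction = len(knob_keys & set(core)) / len(core)
    assert fraction >= 0.9


def test_knobs_verified_by_direct_distance_check(ideal_dimer):
    # independent re-check of every reported knob: its side-chain centroid
    # really has >= 4 partner-chain centroids within the cutoff
    model, _ = ideal_dimer
    cutoff = 7.0
    centroids = {}
    for cid, residues in model.chains.items():
        for res in residues:
            sc = [a.coord for a in res.atoms if a.name not in
                  ("N", "CA", "C", "O")]
            if sc:
                centroids[(cid, res.number)] = np.mean(sc, axis=0)
    for k in find_knobs_into_holes(model, ("A", "B"), cutoff=cutoff):
        kc, kn, _ = k.knob
        partner = "B" if kc == "A" else "A"
        me = centroids[(kc, kn)]
        close = [n for (c, n), p in centroids.items()
                 if c == partner and np.linalg.norm(p - me) <= cutoff]
        assert len(close) >= 4
        assert {h[1] for h in k.hole} <= set(close)
        assert all(h[0] == partner for h in k.hole)


def test_no_knobs_when_chains_separated(ideal_dimer):
    model, _ = ideal_dimer
    apart = model.copy()
    for res in apart.chains["B"]:
        for a in res.atoms:
            a.coord[0] += 30.0
    assert find_knobs_into_holes(apart, ("A", "B")) == []


def test_knobs_symmetric_under_chain_swap(ideal_dimer):
    model, _ = ideal_dimer
    k1 = find_knobs_into_holes(model, ("A", "B"))
    k2 = find_knobs_into_holes(model, ("B", "A"))
    assert {(k.knob, k.hole) for k in k1} == {(k.knob, k.hole) for k in k2}


def test_knob_set_monotone_in_cutoff(ideal_dimer):
    model, _ = ideal_dimer
    tight = {k.knob for k in find_knobs_into_holes(model, ("A", "B"), cutoff=6.5)}
    loose = {k.knob for k in find_knobs_into_holes(model, ("A", "B"), cutoff=7.5)}
    assert tight <= loose


# ---------------------------------------------------------------------------
# salt bridges


def charged_pair(distance, basic_res="LYS"):
    basic_atom = {"LYS": "NZ", "ARG": "NH1", "HIS": "ND1"}[basic_res]
    return make_structure({
        "A": [(10, "GLU", [("CA", "C", (0.0, 0.0, -3.0), 20.0),
                           ("OE1", "O", (0.0, 0.0, 0.0), 20.0),
                           ("OE2", "O", (0.5, 0.0, 0.0), 20.0)])],
        "B": [(14, basic_res, [("CA", "C", (distance, 0.0, -3.0), 20.0),
                               (basic_atom, "N", (distance, 0.0, 0.0), 20.0)])],
    })


def test_salt_bridge_cutoff_semantics():
    # OE2 sits 0.5 A nearer the NZ than OE1, so the minimum charged-atom
    # distance is (separation - 0.5)
    near = charged_pair(3.0)
    far = charged_pair(5.0)
    assert len(find_salt_bridges(near, ("A", "B"))) == 1
    assert find_salt_bridges(far, ("A", "B")) == []
    found = find_salt_bridges(far, ("A", "B"), cutoff=5.5)
    assert len(found) == 1
    assert found[0].min_distance == pytest.approx(4.5)


def test_salt_bridge_identities_and_register():
    s = charged_pair(3.5)
    assign = parse_register("8-21:a..g")  # 10 -> c, 14 -> g
    [b] = find_salt_bridges(s, ("A", "B"), assign=assign)
    assert b.acidic == ("A", 10, "GLU")
    assert b.basic == ("B", 14, "LYS")
    assert b.register_pair == ("c", "g")
    # OE2 is the nearer oxygen (0.5 A toward the NZ)
    assert b.min_distance == pytest.approx(3.0)


def test_histidine_only_on_request():
    s = charged_pair(3.0, basic_res="HIS")
    assert find_salt_bridges(s, ("A", "B")) == []
    assert len(find_salt_bridges(s, ("A", "B"), include_his=True)) == 1


def test_same_chain_pairs_not_reported():
    s = make_structure({
        "A": [(10, "GLU", [("OE1", "O", (0.0, 0.0, 0.0), 20.0)]),
              (11, "LYS", [("NZ", "N", (2.0, 0.0, 0.0), 20.0)])],
        "B": [(5, "ALA", [("CA", "C", (50.0, 0.0, 0.0), 20.0)])],
    })
    assert find_salt_bridges(s, ("A", "B")) == []


# ---------------------------------------------------------------------------
# buried polar core contacts


def test_asn_a_a_prime_pair_detected():
    assign = parse_register("1-14:a..g")
    s = make_structure({
        "A": [(8, "ASN", [("CA", "C", (0.0, 0.0, -3.0), 20.0),
                          ("OD1", "O", (0.0, 0.0, 0.0), 20.0),
                          ("ND2", "N", (0.5, 0.0, 0.0), 20.0)])],
        "B": [(8, "ASN", [("CA", "C", (3.0, 0.0, -3.0), 20.0),
                          ("OD1", "O", (3.0, 0.0, 0.0), 20.0),
                          ("ND2", "N", (2.8, 0.0, 0.0), 20.0)])],
    })
    contacts = find_polar_core_contacts(s, ("A", "B"), assign)
    assert len(contacts) == 1
    (first, second, dmin) = contacts[0]
    assert first == ("A", 8, "ASN") and second == ("B", 8, "ASN")
    assert dmin == pytest.approx(2.3)
    # not reported when the Asn sits off the a position
    off = parse_register("1-14:a..g,phase=b")  # 8 -> b
    assert find_polar_core_contacts(s, ("A", "B"), off) == []


def test_a_lys_g_prime_glu_pair_detected():
    assign = parse_register("1-14:a..g")  # 8 -> a, 7 -> g
    s = make_structure({
        "A": [(8, "LYS", [("CA", "C", (0.0, 0.0, -3.0), 20.0),
                          ("NZ", "N", (0.0, 0.0, 0.0), 20.0)])],
        "B": [(7, "GLU", [("CA", "C", (3.0, 0.0, -3.0), 20.0),
                          ("OE1", "O", (3.0, 0.0, 0.0), 20.0),
                          ("OE2", "O", (3.4, 0.0, 0.0), 20.0)])],
    })
    contacts = find_polar_core_contacts(s, ("A", "B"), assign)
    assert contacts == [(("A", 8, "LYS"), ("B", 7, "GLU"), pytest.approx(3.0))]


# ---------------------------------------------------------------------------
# underwound flagging


def synthetic_profile(values, first_a=1):
    records = []
    for i, v in enumerate(values):
        a = first_a + 7 * i
        records.append(SpacingRecord(heptad=Heptad(a=a, a_prime=a + 7, d=a + 3),
                                     da=v, da_prime=v))
    return SpacingProfile(records=records, chain_pair=("A", "B"))


def test_flag_underwound_median_baseline():
    p = synthetic_profile([7.5, 7.6, 7.5, 9.2, 7.6, 7.5, 7.5])
    flagged = flag_underwound(p)
    assert [h.a for h in flagged] == [22]
    assert underwound_regions(flagged) == [(22, 29)]


def test_flag_underwound_explicit_baseline_and_threshold():
    p = synthetic_profile([7.5, 8.1, 9.2])
    assert [h.a for h in flag_underwound(p, baseline=7.5, threshold=0.5)] == [8, 15]
    assert [h.a for h in flag_underwound(p, baseline=7.5, threshold=1.0)] == [15]
    with pytest.raises(EmptyAggregateError):
        flag_underwound(SpacingProfile(records=[], chain_pair=("A", "B")))


def test_underwound_regions_merge_contiguous():
    hs = [Heptad(a=8, a_prime=15, d=11), Heptad(a=15, a_prime=22, d=18),
          Heptad(a=36, a_prime=43, d=39)]
    assert underwound_regions(hs) == [(8, 22), (36, 43)]


def test_stutter_dimer_flagged_at_insert(stutter_dimer):
    (model, assign), stutter = stutter_dimer
    heptads = enumerate_heptads(assign)
    profile = spacing_profile(model, ("A", "B"), heptads)
    flagged = flag_underwound(profile)
    assert flagged, "stutter region must be flagged"
    regions = underwound_regions(flagged)
    # flagged region overlaps the insert (residues 29-32)
    assert any(start <= 32 and end >= 29 for start, end in regions)
    # far downstream of the insert is regular again
    assert all(h.a < 60 for h in flagged)
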