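"""Coiled-coil core packing analyses.

Knobs-into-holes detection (simplified, side-chain-centroid based), salt
bridges across the dimer interface, buried polar core contacts (a-a'
asparagine hydrogen bonds and a-Lys/g'-Glu pairs), and flagging of
underwound regions from a spacing profile.

All detections are distance-only: the target crystal structures carry no
hydrogens, so hydrogen bonds and salt bridges are scored on heavy-atom
distances with configurable cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyAggregateError
from .geometry import SpacingProfile
from .register import Heptad, HeptadAssignment
from .structure import Residue, StructureModel

log = logging.getLogger(__name__)

#: charged side-chain heavy atoms for salt-bridge scoring
ACIDIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
HIS_ATOMS = ("ND1", "NE2")


@dataclass(frozen=True)
class KnobHole:
    """A knob residue and the 4 nearest partner-chain residues forming its hole."""

    knob: tuple[str, int, str]
    hole: tuple[tuple[str, int], ...]
    mean_contact: float


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple[str, int, str]
    basic: tuple[str, int, str]
    min_distance: float
    register_pair: tuple[str | None, str | None] = (None, None)


def _sidechain_centroid(res: Residue) -> np.ndarray | None:
    atoms = res.sidechain_atoms()
    if not atoms:
        return None
    return np.mean([a.coord for a in atoms], axis=0)


def _chain_centroids(s: StructureModel, chain: str
                     ) -> tuple[list[tuple[int, str]], np.ndarray]:
    info: list[tuple[int, str]] = []
    pts: list[np.ndarray] = []
    for res in s.chains.get(chain, []):
        if res.het or res.is_water:
            continue
        c = _sidechain_centroid(res)
        if c is None:
            log.debug("chain %s residue %d (%s): no side chain, skipped",
                      chain, res.number, res.name)
            continue
        info.append((res.number, res.name))
        pts.append(c)
    return info, np.asarray(pts) if pts else np.empty((0, 3))


def find_knobs_into_holes(s: StructureModel, chains: tuple[str, str],
                          cutoff: float = 7.0) -> list[KnobHole]:
    """Simplified knobs-into-holes: a residue is a knob when its side-chain
    centroid lies within ``cutoff`` of >=4 partner-chain side-chain
    centroids; the 4 nearest of those form the hole."""
    out: list[KnobHole] = []
    for knob_chain, hole_chain in (chains, chains[::-1]):
        k_info, k_pts = _chain_centroids(s, knob_chain)
        h_info, h_pts = _chain_centroids(s, hole_chain)
        if len(k_pts) == 0 or len(h_pts) == 0:
            continue
        d = np.linalg.norm(k_pts[:, None, :] - h_pts[None, :, :], axis=2)
        for i, (num, name) in enumerate(k_info):
            within = np.nonzero(d[i] <= cutoff)[0]
            if len(within) < 4:
                continue
            nearest = within[np.argsort(d[i, within])][:4]
            out.append(KnobHole(
                knob=(knob_chain, num, name),
                hole=tuple((hole_chain, h_info[j][0]) for j in nearest),
                mean_contact=float(d[i, nearest].mean()),
            ))
    out.sort(key=lambda k: (k.knob[0], k.knob[1]))
    return out


def _charged_coords(res: Residue, names: tuple[str, ...]) -> np.ndarray:
    return np.asarray([a.coord for a in res.atoms if a.name in names])


def find_salt_bridges(s: StructureModel, chains: tuple[str, str],
                      cutoff: float = 4.0,
                      assign: HeptadAssignment | None = None,
                      include_his: bool = False) -> list[SaltBridge]:
    """Cross-chain acidic/basic pairs with minimum charged heavy-atom
    distance <= cutoff.  Histidine counts as basic only on request."""
    basic = dict(BASIC_ATOMS)
    if include_his:
        basic["HIS"] = HIS_ATOMS
    out: list[SaltBridge] = []
    c1, c2 = chains
    for ch_a, ch_b in ((c1, c2), (c2, c1)):
        for res_a in s.chains.get(ch_a, []):
            if res_a.name not in ACIDIC_ATOMS:
                continue
            pa = _charged_coords(res_a, ACIDIC_ATOMS[res_a.name])
            if len(pa) == 0:
                continue
            for res_b in s.chains.get(ch_b, []):
                if res_b.name not in basic:
                    continue
                pb = _charged_coords(res_b, basic[res_b.name])
                if len(pb) == 0:
                    continue
                dmin = float(np.min(np.linalg.norm(pa[:, None] - pb[None, :], axis=2)))
                if dmin <= cutoff:
                    letters = (None, None)
                    if assign is not None:
                        letters = (assign.letter(res_a.number), assign.letter(res_b.number))
                    out.append(SaltBridge(
                        acidic=(ch_a, res_a.number, res_a.name),
                        basic=(ch_b, res_b.number, res_b.name),
                        min_distance=dmin, register_pair=letters))
    out.sort(key=lambda b: (b.acidic[0], b.acidic[1], b.basic[0], b.basic[1]))
    return out


#: polar side-chain atoms considered for buried-core hydrogen bonds
_POLAR_SIDECHAIN = {
    "ASN": ("ND2", "OD1"),
    "LYS": ("NZ",),
    "GLU": ("OE1", "OE2"),
}


def find_polar_core_contacts(s: StructureModel, chains: tuple[str, str],
                             assign: HeptadAssignment, cutoff: float = 3.5,
                             ) -> list[tuple[tuple[str, int, str], tuple[str, int, str], float]]:
    """Buried polar contacts at the dimer core.

    Two classes are reported: symmetric a-a' asparagine pairs (the
    dimerization-specificity hydrogen bonds) and a-position lysines paired
    with the preceding g'-position glutamate on the partner chain — the
    favorable interaction that offsets burying a polar a residue.
    """
    out = []
    c1, c2 = chains

    def polar_coords(res: Residue) -> np.ndarray:
        return _charged_coords(res, _POLAR_SIDECHAIN[res.name])

    # a-a' Asn pairs (same letter a on both chains)
    a_positions = set(assign.positions("a"))
    for res1 in s.chains.get(c1, []):
        if res1.name != "ASN" or res1.number not in a_positions:
            continue
        for res2 in s.chains.get(c2, []):
            if res2.name != "ASN" or res2.number not in a_positions:
                continue
            p1, p2 = polar_coords(res1), polar_coords(res2)
            if len(p1) == 0 or len(p2) == 0:
                continue
            dmin = float(np.min(np.linalg.norm(p1[:, None] - p2[None, :], axis=2)))
            if dmin <= cutoff:
                out.append(((c1, res1.number, res1.name),
                            (c2, res2.number, res2.name), dmin))

    # a-Lys / g'-Glu pairs
    g_positions = set(assign.positions("g"))
    for ch_a, ch_b in ((c1, c2), (c2, c1)):
        for res_k in s.chains.get(ch_a, []):
            if res_k.name != "LYS" or res_k.number not in a_positions:
                continue
            for res_e in s.chains.get(ch_b, []):
                if res_e.name != "GLU" or res_e.number not in g_positions:
                    continue
                if abs(res_e.number - res_k.number) > 2:
                    continue
                p1, p2 = polar_coords(res_k), polar_coords(res_e)
                if len(p1) == 0 or len(p2) == 0:
                    continue
                dmin = float(np.min(np.linalg.norm(p1[:, None] - p2[None, :], axis=2)))
                if dmin <= cutoff:
                    out.append(((ch_a, res_k.number, res_k.name),
                                (ch_b, res_e.number, res_e.name), dmin))
    out.sort(key=lambda t: (t[0][0], t[0][1], t[1][0], t[1][1]))
    return out


def flag_underwound(p: SpacingProfile, baseline: float | None = None,
                    threshold: float = 0.5) -> list[Heptad]:
    """Heptads whose mean spacing exceeds baseline + threshold.

    When no baseline is given it is taken as the median of the profile's
    mean column (robust to the inflated region itself).  Returns the
    flagged heptads in order; contiguous runs can be summarized with
    :func:`underwound_regions`.
    """
    vals = [(r.heptad, r.mean) for r in p.records if r.mean is not None]
    if not vals:
        raise EmptyAggregateError("empty spacing profile")
    if baseline is None:
        baseline = float(np.median([v for _, v in vals]))
    return [h for h, v in vals if v > baseline + threshold]


def underwound_regions(flagged: list[Heptad]) -> list[tuple[int, int]]:
    """Group flagged heptads into contiguous (first_a, last_a') regions."""
    regions: list[tuple[int, int]] = []
    for h in sorted(flagged, key=lambda x: x.a):
        if regions and h.a <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], h.a_prime))
        else:
            regions.append((h.a, h.a_prime))
    return regions
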