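"""Core coiled-coil geometry.

Interhelical spacing profiles (the da/da' metric), least-squares rigid
superposition and region RMSDs, helix-axis fitting and inter-axis angles,
Shrake-Rupley solvent-accessible surface area, and cross-chain distances.

The spacing metric follows the classic picture of a parallel dimer: for a
heptad with core position d on one helix and flanking a-positions a, a' on
the partner helix, ``da = |Ca(d) - Ca(a')|``-style Calpha distances are
taken and their mean (da + da')/2 is the per-heptad interhelical spacing.
By default the two chain orderings are averaged (``symmetrize=True``) since
a parallel homodimer makes them near-degenerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (AxisError, CorrespondenceError, EmptyAggregateError,
                     SelectionError, StructureError)
from .register import Heptad
from .structure import Selection, StructureModel, coords_of, select_atoms

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# interhelical spacing


@dataclass
class SpacingRecord:
    """Per-heptad interhelical distances; ``None`` marks missing residues."""

    heptad: Heptad
    da: float | None
    da_prime: float | None

    @property
    def mean(self) -> float | None:
        if self.da is None or self.da_prime is None:
            return None
        return (self.da + self.da_prime) / 2.0


@dataclass
class SpacingProfile:
    records: list[SpacingRecord]
    chain_pair: tuple[str, str]
    structure_label: str = ""

    def means(self) -> list[float | None]:
        return [r.mean for r in self.records]

    def to_tsv(self) -> str:
        """Fixed-format TSV: a, a_prime, d, da, da_prime, mean, structure_label."""
        lines = ["a\ta_prime\td\tda\tda_prime\tmean\tstructure_label"]
        for r in self.records:
            def fmt(x: float | None) -> str:
                return "NA" if x is None else f"{x:.2f}"
            lines.append("\t".join([
                str(r.heptad.a), str(r.heptad.a_prime), str(r.heptad.d),
                fmt(r.da), fmt(r.da_prime), fmt(r.mean), self.structure_label,
            ]))
        return "\n".join(lines) + "\n"


def _ca(s: StructureModel, chain: str, number: int) -> np.ndarray | None:
    res = s.residue(chain, number)
    if res is None:
        return None
    atom = res.ca
    return None if atom is None else atom.coord


def heptad_spacing(s: StructureModel, chains: tuple[str, str], h: Heptad,
                   symmetrize: bool = True) -> SpacingRecord:
    """da/da' Calpha distances for one heptad across the dimer interface.

    ``da = |Ca(d, chain1) - Ca(a, chain2)|`` and
    ``da' = |Ca(d, chain1) - Ca(a', chain2)|``; with ``symmetrize`` each is
    averaged over both chain orderings.  Missing Calpha atoms yield ``None``
    fields rather than an error (profiles keep blank cells).
    """
    c1, c2 = chains
    orderings = [(c1, c2), (c2, c1)] if symmetrize else [(c1, c2)]
    da_vals: list[float] = []
    dap_vals: list[float] = []
    for d_chain, a_chain in orderings:
        d = _ca(s, d_chain, h.d)
        a = _ca(s, a_chain, h.a)
        ap = _ca(s, a_chain, h.a_prime)
        if d is not None and a is not None:
            da_vals.append(float(np.linalg.norm(d - a)))
        if d is not None and ap is not None:
            dap_vals.append(float(np.linalg.norm(d - ap)))
    want = len(orderings)
    da = sum(da_vals) / want if len(da_vals) == want else None
    dap = sum(dap_vals) / want if len(dap_vals) == want else None
    if symmetrize and da is not None:
        log.debug("heptad a=%d per-ordering da=%s da'=%s", h.a, da_vals, dap_vals)
    return SpacingRecord(heptad=h, da=da, da_prime=dap)


def spacing_profile(s: StructureModel, chains: tuple[str, str],
                    heptads: Iterable[Heptad], symmetrize: bool = True,
                    structure_label: str = "") -> SpacingProfile:
    records = [heptad_spacing(s, chains, h, symmetrize) for h in heptads]
    records.sort(key=lambda r: r.heptad.a)
    return SpacingProfile(records=records, chain_pair=tuple(chains),
                          structure_label=structure_label)


def regular_region_mean(p: SpacingProfile,
                        exclude: tuple[int, int] | None = None) -> float:
    """Mean spacing over heptads whose d position lies outside ``exclude``."""
    vals = [r.mean for r in p.records
            if r.mean is not None
            and not (exclude is not None and exclude[0] <= r.heptad.d <= exclude[1])]
    if not vals:
        raise EmptyAggregateError("no heptads left after exclusion")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# superposition


@dataclass
class Transform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthonormal")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of Q onto P (proper rotation only).

    Returns the transform and the post-fit RMSD.  Correspondence is by
    list order; degenerate (collinear) point sets only warn.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise CorrespondenceError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise CorrespondenceError("need at least 3 corresponding points")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - Qc).T @ (P - Pc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        log.warning("near-collinear point set in kabsch; rotation poorly determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Pc - R @ Qc
    transform = Transform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(Q) - P) ** 2, axis=1))))
    return transform, rmsd


def _matched_coords(s1: StructureModel, s2: StructureModel, sel: Selection,
                    chain_map: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray, int]:
    e1 = select_atoms(s1, sel)
    keys2 = {}
    sel2 = Selection(
        chain_ids=None if sel.chain_ids is None else frozenset(
            chain_map[c] for c in sel.chain_ids if c in chain_map),
        residue_ranges=sel.residue_ranges, atom_class=sel.atom_class,
        atom_names=sel.atom_names, include_het=sel.include_het)
    for cid, num, name, coord, _ in select_atoms(s2, sel2):
        keys2[(cid, num, name)] = coord
    P, Q = [], []
    dropped = 0
    for cid, num, name, coord, _ in e1:
        mapped = chain_map.get(cid)
        if mapped is None:
            dropped += 1
            continue
        other = keys2.get((mapped, num, name))
        if other is None:
            dropped += 1
            continue
        P.append(coord)
        Q.append(other)
    dropped += len(keys2) - len(Q)
    return np.asarray(P, float), np.asarray(Q, float), dropped


def region_rmsd(s1: StructureModel, s2: StructureModel, sel: Selection,
                chain_map: Mapping[str, str] | str = "auto",
                ) -> tuple[float, dict[str, str]]:
    """RMSD over a selection after superposing the matched atoms themselves.

    Atoms are matched by (mapped chain, residue number, atom name); unmatched
    atoms are dropped pairwise (count logged).  ``chain_map='auto'`` tries
    both dimer pairings and returns the lower RMSD.
    """
    if chain_map == "auto":
        a1, b1 = (s1.auto_dimer_chains() if sel.chain_ids is None
                  else tuple(sorted(sel.chain_ids))[:2])
        a2, b2 = s2.auto_dimer_chains()
        candidates = [{a1: a2, b1: b2}, {a1: b2, b1: a2}]
    else:
        candidates = [dict(chain_map)]
    best: tuple[float, dict[str, str]] | None = None
    for cmap in candidates:
        P, Q, dropped = _matched_coords(s1, s2, sel, cmap)
        if len(P) < 3:
            continue
        if dropped:
            log.info("chain map %s: dropped %d unmatched atoms", cmap, dropped)
        _, rmsd = kabsch(P, Q)
        if best is None or rmsd < best[0]:
            best = (rmsd, cmap)
    if best is None:
        raise CorrespondenceError("fewer than 3 matched atoms under every chain mapping")
    return best


# ---------------------------------------------------------------------------
# helix axes


@dataclass
class HelixAxis:
    """Least-squares helix axis: a point on the axis, a unit direction
    (oriented N->C) and the residue range it was fitted over."""

    point: np.ndarray
    direction: np.ndarray
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError("direction must be a unit vector")
        self.point = np.asarray(self.point, float)


def helix_axis(s: StructureModel, chain: str,
               residue_range: tuple[int, int]) -> HelixAxis:
    """Axis from sliding-window local origins.

    Local origin i is the centroid of Calpha(i-1..i+2); the axis is the
    least-squares line (principal component) through the origins, oriented
    from the N- to the C-terminal end of the range.
    """
    start, end = residue_range
    cas = []
    for num in range(start, end + 1):
        c = _ca(s, chain, num)
        if c is not None:
            cas.append(c)
    if len(cas) < 7:
        raise AxisError(f"need >=7 consecutive Calpha in {residue_range}, got {len(cas)}")
    cas = np.asarray(cas)
    origins = np.array([cas[i - 1:i + 3].mean(axis=0) for i in range(1, len(cas) - 2)])
    centroid = origins.mean(axis=0)
    _, _, Vt = np.linalg.svd(origins - centroid)
    direction = Vt[0]
    if np.dot(origins[-1] - origins[0], direction) < 0:
        direction = -direction
    return HelixAxis(point=centroid, direction=direction / np.linalg.norm(direction),
                     residue_range=(start, end))


def interaxis_angle(x: HelixAxis, y: HelixAxis, oriented: bool = False) -> float:
    """Angle between axes in degrees: unsigned in [0, 90] by default, or the
    oriented angle in [0, 180] when ``oriented``."""
    c = float(np.dot(x.direction, y.direction))
    if not oriented:
        c = abs(c)
    return math.degrees(math.acos(min(max(c, -1.0), 1.0)))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)

#: package-canonical single-element van der Waals radii (A)
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(s: StructureModel, probe: float = PROBE_RADIUS, n_points: int = 960,
         chains: Sequence[str] | None = None,
         ) -> dict[tuple[str, int], float]:
    """Per-residue Shrake-Rupley solvent-accessible surface area (A^2).

    Numerical quadrature over ``n_points`` quasi-uniform sphere points per
    atom with the package's single-element radii table and a rolling probe
    (default 1.4 A).  Waters/heteroatoms and hydrogens are excluded.
    ``chains`` restricts which chains are present at all (e.g. to strip a
    bound ligand before computing exposure).
    """
    entries = []
    for cid, res, atom in s.iter_atoms():
        if chains is not None and cid not in chains:
            continue
        if res.het or res.is_water or atom.is_hydrogen:
            continue
        radius = SASA_RADII.get(atom.element)
        if radius is None:
            log.warning("element %r has no tabulated radius; using %.2f A",
                        atom.element, DEFAULT_RADIUS)
            radius = DEFAULT_RADIUS
        entries.append((cid, res.number, atom.coord, radius + probe))
    if not entries:
        raise StructureError("no atoms for SASA")

    coords = np.array([e[2] for e in entries])
    radii = np.array([e[3] for e in entries])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    areas: dict[tuple[str, int], float] = {}
    for i, (cid, num, _, _) in enumerate(entries):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            d2 = np.sum((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2, axis=2)
            # points exactly on a neighbor sphere (e.g. duplicated atoms)
            # count as buried; the relative epsilon absorbs rounding in d2
            buried = np.any(d2 <= radii[neighbors][None, :] ** 2 * (1 + 1e-9),
                            axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        area = 4.0 * math.pi * radii[i] ** 2 * accessible / n_points
        key = (cid, num)
        areas[key] = areas.get(key, 0.0) + area
    return areas


def sasa_sum(areas: Mapping[tuple[str, int], float],
             residues: Iterable[tuple[str, int]]) -> float:
    """Sum per-residue SASA over (chain, residue-number) keys."""
    return float(sum(areas.get(key, 0.0) for key in residues))


# ---------------------------------------------------------------------------
# misc distances


def cross_chain_ca_distance(s: StructureModel, residue_number: int,
                            chains: tuple[str, str]) -> float:
    """Calpha-Calpha distance for one residue number across the two chains."""
    c1, c2 = chains
    if c1 == c2:
        log.warning("same chain %r passed twice: distance is 0 by construction", c1)
    a = _ca(s, c1, residue_number)
    b = _ca(s, c2, residue_number)
    if a is None or b is None:
        missing = c1 if a is None else c2
        raise SelectionError(f"no Calpha for residue {residue_number} in chain {missing}")
    return float(np.linalg.norm(a - b))
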