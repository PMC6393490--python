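"""Synthetic coiled-coil fixtures.

Every analysis stage in this package can be exercised without external
data: this module generates ideal parallel dimeric coiled coils from a
Crick-style parameterization (optionally carrying a register stutter with
local unwinding and painted B-factors), Gaussian-perturbed coordinate
ensembles standing in for an MD trajectory, and simulated anisotropy
titrations and CD melting curves.

All generators are pure functions of (parameters, seed).

Geometry
--------
Chain A Calpha positions follow a minor helix of radius ``R1`` wound
around a superhelical curve of radius ``R0``::

    A(t) = (R0 cos(w0 t), R0 sin(w0 t), rise * t)
    r(t) = A(t) + R1 (cos(psi(t)) u(t) + sin(psi(t)) v(t))

with ``u`` the outward radial unit vector, ``v = T x u`` (T the curve
tangent), ``w1 = 2 pi / residues_per_turn`` and ``w0 = w1 - 4 pi / 7`` so
that the interface phase ``psi = (w1 - w0) t + psi0`` advances exactly two
turns per heptad and the a/d positions keep facing the partner chain.
Chain B is chain A rotated 180 degrees about the superhelical axis, giving
a C2-symmetric parallel dimer.  Each residue gets a CA atom and a CB stub
1.5 A outward along the minor radial direction (a usable side-chain
centroid for packing analyses).

A stutter insert locally delays the interface phase: the +4-residue
register shift is compensated by a phase correction ramped across the
insert, and ``local_unwind`` adds a transient extra lag (a triangular bump
over the insert +/- 4 residues), which elevates the interhelical spacing
exactly around the insert, as real stutters do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding import BindingModel, MeltingCurve, TitrationSet, fa_model
from .errors import CoilkitError
from .register import LETTERS, HeptadAssignment, parse_register
from .structure import Atom, Ensemble, Residue, StructureModel

#: residue name given to core (a/d) positions vs the rest
CORE_RESNAME = "LEU"
OTHER_RESNAME = "ALA"


@dataclass(frozen=True)
class CrickParams:
    """Ideal-dimer construction parameters (canonical dimer defaults)."""

    n_res: int = 117  # matches the length of the studied construct chains
    R0: float = 4.9            # superhelical radius, A
    R1: float = 2.26           # minor (alpha-helical) radius, A
    rise: float = 1.51         # rise per residue along the superhelical axis, A
    residues_per_turn: float = 3.62
    interface_phase: float = 180.0 + 180.0 / 7.0  # psi of a-positions, degrees
    orientation: str = "parallel"

    def __post_init__(self) -> None:
        if self.R0 < 0 or self.R1 <= 0 or self.rise <= 0 or self.n_res < 8:
            raise CoilkitError("invalid Crick parameters")
        if self.orientation != "parallel":
            raise CoilkitError("only parallel dimers are generated")


@dataclass(frozen=True)
class StutterSpec:
    """A register insert: 4 residues = stutter, 3 = stammer, 1 = skip."""

    insert_after: int
    pattern: str = "abcd"
    local_unwind: float = 20.0  # degrees of transient extra interface-phase lag

    def __post_init__(self) -> None:
        if len(self.pattern) not in (1, 3, 4):
            raise CoilkitError("insert pattern length must be 1, 3 or 4")
        if set(self.pattern) - set(LETTERS):
            raise CoilkitError("insert pattern letters must be a-g")


def _register_spec(n_res: int, stutter: StutterSpec | None) -> str:
    if stutter is None:
        return f"1-{n_res}:a..g"
    ins_start = stutter.insert_after + 1
    ins_end = ins_start + len(stutter.pattern) - 1
    if not 1 < ins_start <= n_res - len(stutter.pattern):
        raise CoilkitError("stutter insert outside chain")
    down_phase = LETTERS[(ins_end + 1 - len(stutter.pattern) - 1) % 7]
    parts = [f"1-{stutter.insert_after}:a..g",
             f"{ins_start}-{ins_end}:{stutter.pattern}"]
    if ins_end < n_res:
        phase = "" if down_phase == "a" else f",phase={down_phase}"
        parts.append(f"{ins_end + 1}-{n_res}:a..g{phase}")
    return ";".join(parts)


def _phase_correction(t: np.ndarray, stutter: StutterSpec | None) -> np.ndarray:
    """Interface-phase lag (radians) per 0-based residue index."""
    if stutter is None:
        return np.zeros_like(t, dtype=float)
    ins_len = len(stutter.pattern)
    i0 = stutter.insert_after          # index of last pre-insert residue is i0-1
    # permanent correction: the +ins_len register shift advances psi at the
    # downstream a/d positions by ins_len * 4pi/7 (mod 2pi); undo it, ramped
    # across the insert
    shift = -(ins_len * 4.0 * math.pi / 7.0) % (2.0 * math.pi)
    if shift > math.pi:
        shift -= 2.0 * math.pi
    ramp = np.clip((t - (i0 - 1)) / ins_len, 0.0, 1.0)
    out = shift * ramp
    # transient extra lag: triangular bump over the insert +/- 4 residues
    center = i0 - 1 + ins_len / 2.0
    width = ins_len / 2.0 + 4.0
    bump = np.clip(1.0 - np.abs(t - center) / width, 0.0, None)
    out -= math.radians(stutter.local_unwind) * bump
    return out


def build_crick_dimer(p: CrickParams = CrickParams(),
                      stutter: StutterSpec | None = None,
                      seed: int = 0,
                      bfactors: np.ndarray | float = 20.0,
                      ) -> tuple[StructureModel, HeptadAssignment]:
    """Build an ideal two-chain Calpha/CB dimer and its register.

    ``bfactors`` paints per-residue B-factors (scalar or length-``n_res``
    array; both chains get the same profile).  ``seed`` is accepted for API
    uniformity; the construction is deterministic.
    """
    del seed  # deterministic construction
    assign = parse_register(_register_spec(p.n_res, stutter))

    t = np.arange(p.n_res, dtype=float)
    w1 = 2.0 * math.pi / p.residues_per_turn
    w0 = w1 - 4.0 * math.pi / 7.0
    phi0 = w0 * t
    psi = (w1 - w0) * t + math.radians(p.interface_phase) + _phase_correction(t, stutter)

    axis = np.column_stack([p.R0 * np.cos(phi0), p.R0 * np.sin(phi0), p.rise * t])
    u = np.column_stack([np.cos(phi0), np.sin(phi0), np.zeros_like(t)])
    tangent = np.column_stack([-p.R0 * w0 * np.sin(phi0),
                               p.R0 * w0 * np.cos(phi0),
                               np.full_like(t, p.rise)])
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    v = np.cross(tangent, u)
    radial = np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v
    ca = axis + p.R1 * radial
    cb = ca + 1.5 * radial

    b = np.broadcast_to(np.asarray(bfactors, float), (p.n_res,))

    model = StructureModel(source="coilkit:build_crick_dimer")
    rot = np.diag([-1.0, -1.0, 1.0])  # C2 about the superhelical (z) axis
    for cid, transform in (("A", np.eye(3)), ("B", rot)):
        residues = []
        for i in range(p.n_res):
            number = i + 1
            letter = assign.letter(number)
            name = CORE_RESNAME if letter in ("a", "d") else OTHER_RESNAME
            residues.append(Residue(
                number=number, name=name,
                atoms=[
                    Atom("CA", "C", transform @ ca[i], bfactor=float(b[i])),
                    Atom("CB", "C", transform @ cb[i], bfactor=float(b[i])),
                ],
            ))
        model.chains[cid] = residues
    return model, assign


# ---------------------------------------------------------------------------
# ensembles


def _sigma_for(sigma_profile, chain: str, number: int) -> float:
    if np.isscalar(sigma_profile):
        return float(sigma_profile)
    if isinstance(sigma_profile, dict):
        if (chain, number) in sigma_profile:
            return float(sigma_profile[(chain, number)])
        return float(sigma_profile.get(number, 0.0))
    raise CoilkitError("sigma_profile must be a scalar or a dict")


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random rotation (QR-based) and a translation within +/-20 A."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-20.0, 20.0, 3)


def perturb_ensemble(s: StructureModel, sigma_profile, n_frames: int,
                     seed: int, rigid_transforms: bool = False) -> Ensemble:
    """Frames = base coordinates + isotropic Gaussian noise per atom, scaled
    by the residue's sigma; optionally each frame also gets an independent
    random rigid transform (to exercise superposition removal)."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        frame = s.copy()
        for cid, res, atom in frame.iter_atoms():
            sigma = _sigma_for(sigma_profile, cid, res.number)
            if sigma < 0:
                raise CoilkitError("sigma must be >= 0")
            if sigma > 0:
                atom.coord[:] = atom.coord + rng.normal(0.0, sigma, 3)
        if rigid_transforms:
            Q, trans = _random_rigid(rng)
            frame = frame.transformed(Q, trans)
        frames.append(frame)
    return Ensemble(frames)


# ---------------------------------------------------------------------------
# titrations and melts


def simulate_titration(m: BindingModel, P_values, noise_sd: float,
                       replicates: int = 1, seed: int = 0) -> TitrationSet:
    """Observed anisotropy = model + Gaussian(0, noise_sd), seeded."""
    rng = np.random.default_rng(seed)
    P = np.repeat(np.asarray(P_values, float), replicates)
    FA = fa_model(m, P)
    if noise_sd > 0:
        FA = FA + rng.normal(0.0, noise_sd, P.shape)
    return TitrationSet(P=P, FA=np.asarray(FA, float), l_total=m.l_total, unit=m.unit)


def simulate_melt(tm: float, cooperativity: float,
                  baselines: tuple[float, float] = (-22000.0, -3000.0),
                  T_grid=None, noise_sd: float = 0.0, seed: int = 0,
                  drift: tuple[float, float] = (0.0, 0.0)) -> MeltingCurve:
    """Two-state logistic melt between (optionally drifting) baselines.

    theta(T) = pre(T) + (post(T) - pre(T)) / (1 + exp(-(T - tm) * k))
    with k the ``cooperativity`` slope (1/C).  The default grid is the
    20-90 C range at 1 C steps; with flat baselines the derivative maximum
    sits exactly at ``tm``.
    """
    if T_grid is None:
        T_grid = np.arange(20.0, 90.0 + 0.5, 1.0)
    T = np.asarray(T_grid, float)
    if np.any(np.diff(T) <= 0):
        raise CoilkitError("T_grid must be strictly increasing")
    pre = baselines[0] + drift[0] * (T - T[0])
    post = baselines[1] + drift[1] * (T - T[0])
    frac = 1.0 / (1.0 + np.exp(-np.clip((T - tm) * cooperativity, -500, 500)))
    theta = pre + (post - pre) * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, T.shape)
    return MeltingCurve(T=T, theta=theta)
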