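import numpy as np
import pytest

import coilkit as ck
from coilkit.structure import Atom, Residue, StructureModel
from coilkit.synthetic import CrickParams, StutterSpec, build_crick_dimer


@pytest.fixture(scope="session")
def ideal_dimer():
    """Default ideal parallel dimer plus its register."""
    return build_crick_dimer(CrickParams(), seed=0)


@pytest.fixture(scope="session")
def stutter_dimer():
    """Dimer with an abcd stutter inserted after residue 28 (a g position)."""
    params = CrickParams()
    stutter = StutterSpec(insert_after=28, local_unwind=20.0)
    return build_crick_dimer(params, stutter, seed=0), stutter


def make_structure(chains):
    """Build a StructureModel from {chain: [(num, resname, [(atom, elem, xyz, b)])]}."""
    s = StructureModel(source="test")
    for cid, residues in chains.items():
        s.chains[cid] = [
            Residue(num, name,
                    [Atom(an, el, np.asarray(xyz, float), bfactor=b)
                     for an, el, xyz, b in atoms])
            for num, name, atoms in residues
        ]
    return s


def straight_dimer(n_res=21, separation=8.0, rise=1.5):
    """Two straight parallel poly-Ala Calpha helices along z, ``separation``
    apart, identical z-registration (a degenerate test geometry, not Crick)."""
    chains = {}
    for cid, x in (("A", 0.0), ("B", separation)):
        chains[cid] = [
            (i + 1, "ALA", [("CA", "C", (x, 0.0, rise * i), 20.0)])
            for i in range(n_res)
        ]
    return make_structure(chains)


def random_rigid(rng):
    """A uniform-ish random proper rotation and translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-30, 30, 3)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementations they check)


def mass_action_fa(L, P, kd, fa_min, fa_max):
    """Bound-fraction oracle: solve [PL] from mass action by bisection on
    (L-x)(P-x)/kd - x = 0 over [0, min(L, P)], then FA = fa_min +
    (fa_max - fa_min) * x / L.  Numerically independent of the closed form."""
    from scipy.optimize import brentq
    if P == 0 or L == 0:
        return fa_min
    f = lambda x: (L - x) * (P - x) / kd - x
    hi = min(L, P)
    x = brentq(f, 0.0, hi, xtol=1e-16, rtol=1e-15, maxiter=200)
    return fa_min + (fa_max - fa_min) * x / L


def brute_force_min_rmsd(P, Q, seed=0):
    """Minimum RMSD over rotations by quaternion sampling with shrinking
    local refinement (translation removed by centering)."""
    rng = np.random.default_rng(seed)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def quat_to_rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def rmsd_for(q):
        R = quat_to_rot(q)
        return np.sqrt(np.mean(np.sum((Q @ R.T - P) ** 2, axis=1)))

    candidates = rng.normal(size=(2000, 4))
    best_q = min(candidates, key=rmsd_for)
    best = rmsd_for(best_q)
    for scale in (0.3, 0.1, 0.03, 0.01, 0.003, 0.001):
        for _ in range(120):
            q = best_q + rng.normal(scale=scale, size=4)
            r = rmsd_for(q)
            if r < best:
                best, best_q = r, q
    return best
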