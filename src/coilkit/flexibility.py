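"""Flexibility statistics.

Three complementary views of coiled-coil mobility:

* **Normalized B-factors** of one chain against the whole structure.  With
  B the per-residue mean of atom B-factors, B_ave and B_std the mean and
  sample standard deviation over all N residues of the structure, and n
  the number of residues of the examined chain, the normalized value is ::

      BN' = (B - B_ave) / ( (B_std / sqrt(n)) * sqrt((N - n) / (N - 1)) )

  i.e. a location-normalized score with a finite-population correction.
  Reported values are additionally averaged over a 3-residue moving window
  (shrinking to 2 at chain termini).

* **Ensemble RMSF** per atom of a selection, after iterative superposition
  of every frame onto the ensemble mean (two refinement passes), so the
  result is invariant to arbitrary per-frame rigid motion.

* **Per-heptad spacing fluctuation**: mean and sample SD over frames of the
  (da + da')/2 interhelical spacing, indexed by the heptad's d residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import DegenerateVarianceError
from .geometry import heptad_spacing, kabsch
from .register import Heptad
from .structure import Ensemble, Selection, StructureModel, coords_of, select_atoms


@dataclass
class BFactorProfile:
    residues: list[int]
    B: np.ndarray          # per-residue B (mean of atom B-factors), A^2
    B_ave: float           # over all N residues of the structure
    B_std: float           # sample SD over all N residues
    N: int                 # residues in structure
    n: int                 # residues in examined chain
    BN: np.ndarray         # normalized values, dimensionless
    windowed: np.ndarray   # 3-residue moving average of BN


def _moving_window3(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        out[i] = x[lo:hi].mean()
    return out


def _residue_b(s: StructureModel) -> dict[tuple[str, int], float]:
    out = {}
    for cid, residues in s.chains.items():
        for res in residues:
            if res.het or res.is_water:
                continue
            bs = [a.bfactor for a in res.atoms if not a.is_hydrogen]
            if bs:
                out[(cid, res.number)] = float(np.mean(bs))
    return out


def normalize_bfactors(s: StructureModel, chain: str) -> BFactorProfile:
    """Normalized B-factor profile of one chain (see module docstring)."""
    per_res = _residue_b(s)
    all_b = np.array(list(per_res.values()))
    N = len(all_b)
    if N < 2:
        raise DegenerateVarianceError("need at least 2 residues with B-factors")
    chain_items = sorted((num, b) for (cid, num), b in per_res.items() if cid == chain)
    n = len(chain_items)
    if n == 0:
        raise DegenerateVarianceError(f"chain {chain!r} has no residues with B-factors")
    if n == N:
        raise DegenerateVarianceError(
            "chain covers the whole structure (n == N): sqrt((N-n)/(N-1)) = 0")
    b_ave = float(all_b.mean())
    b_std = float(all_b.std(ddof=1))
    if b_std == 0.0:
        raise DegenerateVarianceError("B-factors have zero variance across the structure")
    denom = (b_std / math.sqrt(n)) * math.sqrt((N - n) / (N - 1))
    residues = [num for num, _ in chain_items]
    B = np.array([b for _, b in chain_items])
    BN = (B - b_ave) / denom
    return BFactorProfile(residues=residues, B=B, B_ave=b_ave, B_std=b_std,
                          N=N, n=n, BN=BN, windowed=_moving_window3(BN))


@dataclass
class RMSFProfile:
    """Per-selected-atom RMSF (A), keyed by (chain, residue number, atom name)."""

    keys: list[tuple[str, int, str]]
    rmsf: np.ndarray

    def for_chain(self, chain: str) -> tuple[list[int], np.ndarray]:
        idx = [i for i, k in enumerate(self.keys) if k[0] == chain]
        return [self.keys[i][1] for i in idx], self.rmsf[idx]


def ensemble_rmsf(e: Ensemble, sel: Selection, n_iter: int = 2) -> RMSFProfile:
    """RMSF per selected atom after iterative mean-structure superposition."""
    frames = []
    keys: list[tuple[str, int, str]] | None = None
    for frame in e.frames:
        entries = select_atoms(frame, sel, strict=True)
        k = [(c, r, a) for c, r, a, _, _ in entries]
        if keys is None:
            keys = k
        frames.append(coords_of(entries))
    X = np.stack(frames)  # (n_frames, n_atoms, 3)
    if len(X) == 1:
        import logging
        logging.getLogger(__name__).warning("single-frame ensemble: RMSF is zero")
        return RMSFProfile(keys=keys, rmsf=np.zeros(X.shape[1]))
    mean = X[0].copy()
    for _ in range(n_iter):
        aligned = []
        for i in range(len(X)):
            t, _ = kabsch(mean, X[i])
            aligned.append(t.apply(X[i]))
        X = np.stack(aligned)
        mean = X.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return RMSFProfile(keys=keys, rmsf=rmsf)


def ensemble_spacing_sd(e: Ensemble, chains: tuple[str, str],
                        heptads: Iterable[Heptad], symmetrize: bool = True,
                        ) -> list[tuple[int, float | None, float | None]]:
    """Per-heptad (d residue, mean, sample SD) of the spacing over frames.

    The abscissa is the heptad's d residue number.  Heptads with missing
    residues in any frame propagate ``None``.
    """
    out = []
    for h in heptads:
        vals = []
        ok = True
        for frame in e.frames:
            rec = heptad_spacing(frame, chains, h, symmetrize=symmetrize)
            if rec.mean is None:
                ok = False
                break
            vals.append(rec.mean)
        if not ok:
            out.append((h.d, None, None))
            continue
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out.append((h.d, float(arr.mean()), sd))
    return out
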