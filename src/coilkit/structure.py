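"""Structure I/O and atom selection.

Reads PDB (and mmCIF) coordinate files into a small hierarchical model
(chains -> residues -> atoms) keeping author residue numbering and
per-atom B-factors, which downstream geometry and flexibility analyses
address directly.  gemmi does the actual parsing/writing; this module owns
the in-memory model, the altloc/hydrogen conventions and the deterministic
atom-selection order.

Conventions
-----------
* Author residue numbering is the only addressing scheme; no renumbering.
* Altlocs are resolved to the highest-occupancy conformer on read
  (ties broken by altloc character).
* Hydrogens are retained but flagged; every analysis selection excludes
  them (crystal structures lack them; synthetic models are heavy-atom only).
* Waters and heteroatoms are kept in the model but excluded from
  selections by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import ParseError, SelectionError, StructureError, TopologyError

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: canonical intra-residue atom order used for deterministic selections
_ATOM_RANK = {name: i for i, name in enumerate(BACKBONE_ATOMS + ("CB",))}


def _atom_sort_key(name: str) -> tuple[int, str]:
    return (_ATOM_RANK.get(name, len(_ATOM_RANK)), name)


@dataclass
class Atom:
    """A single atom: name, element symbol, position (A), B-factor, occupancy."""

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    het: bool = False  # HETATM record (incl. waters)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy side-chain atoms (everything but backbone N/CA/C/O/OXT)."""
        skip = set(BACKBONE_ATOMS) | {"OXT"}
        return [a for a in self.atoms if a.name not in skip and not a.is_hydrogen]

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT")


@dataclass
class StructureModel:
    """One coordinate model: mapping chain id -> ordered residues."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    model_id: int = 1
    source: str = ""

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residue(self, chain_id: str, number: int) -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.number == number:
                return r
        return None

    def iter_atoms(self) -> Iterable[tuple[str, Residue, Atom]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def copy(self) -> "StructureModel":
        out = StructureModel(model_id=self.model_id, source=self.source)
        for cid, residues in self.chains.items():
            out.chains[cid] = [
                Residue(
                    r.number,
                    r.name,
                    [Atom(a.name, a.element, a.coord.copy(), a.bfactor,
                          a.occupancy, a.altloc, a.is_hydrogen) for a in r.atoms],
                    r.insertion_code,
                    r.het,
                )
                for r in residues
            ]
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped to R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = self.copy()
        for _, _, atom in out.iter_atoms():
            atom.coord[:] = rotation @ atom.coord + translation
        return out

    def protein_chains(self) -> list[str]:
        """Chain ids sorted by number of non-water residues, longest first."""
        sizes = {
            cid: sum(1 for r in residues if not r.is_water)
            for cid, residues in self.chains.items()
        }
        return sorted(sizes, key=lambda c: (-sizes[c], c))

    def auto_dimer_chains(self) -> tuple[str, str]:
        """Pick the two longest protein chains as the coiled-coil dimer."""
        ids = self.protein_chains()
        if len(ids) < 2:
            raise StructureError("auto chain detection needs at least two chains")
        pair = (ids[0], ids[1])
        log.warning("auto-detected dimer chains %s (specify chains to override)", pair)
        return pair


@dataclass
class Ensemble:
    """Ordered coordinate frames over an identical topology."""

    frames: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError("ensemble has no frames")
        ref = _inventory(self.frames[0])
        for i, frame in enumerate(self.frames[1:], start=2):
            inv = _inventory(frame)
            if inv != ref:
                first = sorted(set(ref) ^ set(inv))[0]
                raise TopologyError(
                    f"frame {i} atom inventory differs from frame 1 "
                    f"(first mismatch: {first})"
                )

    def __len__(self) -> int:
        return len(self.frames)


def _inventory(s: StructureModel) -> tuple:
    return tuple(
        (cid, res.number, res.name, atom.name)
        for cid, res, atom in s.iter_atoms()
    )


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    ``chain_ids=None`` means all chains; ``residue_ranges=None`` means all
    residues.  ``atom_class`` is one of ``all-heavy``, ``backbone``,
    ``calpha`` or ``named-set`` (then ``atom_names`` applies).
    """

    chain_ids: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_class: str = "all-heavy"
    atom_names: frozenset[str] = frozenset()
    include_het: bool = False

    def __post_init__(self) -> None:
        if self.atom_class not in ("all-heavy", "backbone", "calpha", "named-set"):
            raise SelectionError(f"unknown atom class {self.atom_class!r}")
        if self.residue_ranges is not None:
            for start, end in self.residue_ranges:
                if end < start:
                    raise SelectionError(f"empty residue range {start}-{end}")

    def _wants_residue(self, number: int) -> bool:
        if self.residue_ranges is None:
            return True
        return any(start <= number <= end for start, end in self.residue_ranges)

    def _wants_atom(self, name: str) -> bool:
        if self.atom_class == "calpha":
            return name == "CA"
        if self.atom_class == "backbone":
            return name in BACKBONE_ATOMS
        if self.atom_class == "named-set":
            return name in self.atom_names
        return True  # all-heavy: hydrogens filtered separately


def selection(chains: Sequence[str] | None = None,
              ranges: Sequence[tuple[int, int]] | None = None,
              atom_class: str = "all-heavy",
              atom_names: Sequence[str] = ()) -> Selection:
    """Convenience constructor for :class:`Selection`."""
    return Selection(
        chain_ids=None if chains is None else frozenset(chains),
        residue_ranges=None if ranges is None else tuple((int(a), int(b)) for a, b in ranges),
        atom_class=atom_class,
        atom_names=frozenset(atom_names),
    )


def select_atoms(s: StructureModel, sel: Selection, strict: bool = False
                 ) -> list[tuple[str, int, str, np.ndarray, float]]:
    """Resolve a selection into ``(chain, resnum, atom name, coord, bfactor)``
    tuples in deterministic (chain, residue, canonical atom name) order."""
    if sel.chain_ids is not None:
        missing = set(sel.chain_ids) - set(s.chains)
        if missing:
            raise SelectionError(f"chains not in structure: {sorted(missing)}")
        chain_ids = sorted(sel.chain_ids)
    else:
        chain_ids = sorted(s.chains)

    out: list[tuple[str, int, str, np.ndarray, float]] = []
    for cid in chain_ids:
        for res in s.chains[cid]:
            if (res.het or res.is_water) and not sel.include_het:
                continue
            if not sel._wants_residue(res.number):
                continue
            atoms = [a for a in res.atoms
                     if not a.is_hydrogen and sel._wants_atom(a.name)]
            atoms.sort(key=lambda a: _atom_sort_key(a.name))
            out.extend((cid, res.number, a.name, a.coord, a.bfactor) for a in atoms)
    if strict and not out:
        raise SelectionError("selection resolved to zero atoms (strict mode)")
    return out


def coords_of(entries: list[tuple[str, int, str, np.ndarray, float]]) -> np.ndarray:
    """Stack selection entries into an (N, 3) coordinate array."""
    if not entries:
        return np.empty((0, 3))
    return np.array([e[3] for e in entries], dtype=float)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom name (tie: first altloc)."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _neg_char(atom.altloc)) > (prev.occupancy, _neg_char(prev.altloc)):
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _neg_char(c: str) -> int:
    # higher key wins; earlier altloc letter should win ties
    return -ord(c) if c else 1


def _convert_model(model: gemmi.Model, source: str) -> StructureModel:
    out = StructureModel(model_id=int(model.num), source=source)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    bfactor=a.b_iso,
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                    is_hydrogen=a.is_hydrogen(),
                )
                for a in res
            ]
            residues.append(
                Residue(
                    number=res.seqid.num,
                    name=res.name,
                    atoms=_resolve_altlocs(atoms),
                    insertion_code=(res.seqid.icode or "").strip(),
                    het=res.het_flag == "H",
                )
            )
        if residues:
            out.chains[chain.name] = residues
    if not any(out.chains.values()):
        raise StructureError(f"{source}: empty coordinate set")
    return out


def _read_gemmi(path: str | Path, format: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    return st


def read_structure(path: str | Path, format: str = "auto",
                   model_id: int | None = None) -> StructureModel:
    """Read a PDB/mmCIF file; return the first model unless ``model_id`` given."""
    st = _read_gemmi(path, format)
    if model_id is None:
        model = st[0]
    else:
        model = next((m for m in st if int(m.num) == model_id), None)
        if model is None:
            raise StructureError(f"{path}: no model {model_id}")
    return _convert_model(model, source=str(path))


def read_ensemble(path: str | Path, format: str = "auto") -> Ensemble:
    """Read a multi-model PDB file as an ordered ensemble of frames."""
    st = _read_gemmi(path, format)
    frames = [_convert_model(m, source=f"{path}#model{m.num}") for m in st]
    return Ensemble(frames)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(s: StructureModel, model_num: int) -> gemmi.Model:
    model = gemmi.Model(model_num)
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.b_iso = atom.bfactor
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    return model


def write_structure(s: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file."""
    write_ensemble(Ensemble([s]), path)


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write frames as a multi-model PDB file (the ensemble interchange format)."""
    st = gemmi.Structure()
    for i, frame in enumerate(e.frames, start=1):
        st.add_model(_to_gemmi(frame, i))
    st.setup_entities()
    st.write_pdb(str(path))
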