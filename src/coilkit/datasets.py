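"""Bundled and user-supplied reference data.

The packaged NEMO register reconstructs the published heptad table for the
coiled-coil-stabilized NEMO construct (numbering 23-139, stutter at 79-82).

Deposited crystal structures are *not* bundled: to run the structure-based
comparisons (apo NEMO-EEAA 6MI3, NEMO-I65M 6MI4, the IKKbeta-bound complex
3BRV, the GCN4 leucine zipper 4DMD), download the PDB entries and place
them under ``<repo>/data/pdb/<id>.pdb`` (lower-case id), or point
``deposited_structure`` at a directory of your choice.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .errors import ParseError
from .register import HeptadAssignment, parse_register
from .structure import StructureModel, read_structure

#: default search location for user-downloaded deposited structures
DEFAULT_PDB_DIR = Path(__file__).resolve().parents[2] / "data" / "pdb"


def nemo_register() -> HeptadAssignment:
    """The packaged NEMO-EEAA heptad register (construct numbering 23-139)."""
    text = (resources.files("coilkit") / "data" / "registers" /
            "nemo_eeaa.txt").read_text()
    return parse_register(text)


def deposited_structure(pdb_id: str, pdb_dir: str | Path | None = None
                        ) -> StructureModel:
    """Load a user-downloaded deposited structure by PDB id.

    Looks for ``<pdb_dir>/<id>.pdb`` (also ``.cif``); raises a
    :class:`ParseError` with download instructions when absent.
    """
    base = Path(pdb_dir) if pdb_dir is not None else DEFAULT_PDB_DIR
    pdb_id = pdb_id.lower()
    for suffix in (".pdb", ".ent", ".cif"):
        path = base / f"{pdb_id}{suffix}"
        if path.exists():
            return read_structure(path)
    raise ParseError(
        f"deposited structure {pdb_id!r} not found under {base}; download it "
        f"from the Protein Data Bank (https://files.rcsb.org/download/"
        f"{pdb_id.upper()}.pdb) and place it there")
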