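"""Minimal atomic data model and PDB I/O.

Reading goes through gemmi and keeps only what the search engine needs:
heavy ATOM records of the first model, one alternate location per atom.
No chemistry is inferred beyond what the records carry.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["Atom", "Structure", "EmptyStructureError", "read_pdb", "write_pdb"]


class EmptyStructureError(ValueError):
    """Raised when a PDB file yields no usable ATOM records."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One PDB ATOM record (heavy atom, single location)."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    coords: tuple[float, float, float]
    element: str

    def __post_init__(self) -> None:
        if not self.name.strip() or not self.res_name.strip():
            raise ValueError("atom name and residue name must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        """Identity of the residue this atom belongs to."""
        return (self.chain_id, self.res_seq, self.i_code, self.res_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclasses.dataclass
class Structure:
    """An ordered list of atoms plus its residue grouping."""

    structure_id: str
    atoms: list[Atom]

    @property
    def residues(self) -> dict[tuple[str, int, str, str], list[Atom]]:
        """Group atoms by (chain_id, res_seq, i_code, res_name), file order."""
        groups: dict[tuple[str, int, str, str], list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_id, []).append(atom)
        return groups

    def __len__(self) -> int:
        return len(self.atoms)


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a Structure.

    Keeps ATOM records of the first model only; skips HETATM, hydrogens
    (H/D) and alternate locations other than "" / "A".

    Raises
    ------
    EmptyStructureError
        If no ATOM record survives the filters.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise EmptyStructureError(f"no model in {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            for at in residue:
                if at.element.name in ("H", "D"):
                    continue
                if at.altloc not in ("\0", "", "A"):
                    continue
                alt = "" if at.altloc in ("\0", "") else at.altloc
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name.strip(),
                        alt_loc=alt,
                        res_name=residue.name.strip(),
                        chain_id=chain.name,
                        res_seq=residue.seqid.num,
                        i_code=(residue.seqid.icode or "").strip(),
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        element=at.element.name,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"no ATOM records in {path}")
    return Structure(structure_id=path.stem, atoms=atoms)


def write_pdb(atoms: list[Atom], remarks: list[str], path: str | Path) -> None:
    """Write atoms as fixed-column PDB ATOM records preceded by REMARK lines.

    Round-trips names, residue identities and coordinates to 3 decimals.
    """
    if not atoms:
        raise ValueError("cannot write an empty atom list")
    lines = [f"REMARK   6 {r}" for r in remarks]
    for i, a in enumerate(atoms, start=1):
        # PDB convention: 4-char atom-name field starts at column 13 unless
        # the element symbol occupies two characters.
        name = a.name if len(a.name) >= 4 or len(a.element) == 2 else f" {a.name}"
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.alt_loc or ' '}{a.res_name:>3s} "
            f"{a.chain_id:1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
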