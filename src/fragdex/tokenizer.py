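"""Spatial pagination and word detection.

A structure is partitioned into non-overlapping cubic *pages* (default
15 Å wide, the retrieval unit of the engine) on a lattice anchored at the
coordinate origin, and every occurrence of every lexicon word is detected
by residue/atom names and residue adjacency. Each word instance is
assigned to exactly one page — the page containing its centroid — so an
instance straddling a cube boundary stays whole, at the cost that a query
can miss motifs whose partners fall in different pages.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .lexicon import STANDARD_RESIDUES, WILDCARD, Lexicon, WordVariant
from .structure import Atom, Structure

__all__ = [
    "DEFAULT_CELL_SIZE",
    "PageKey",
    "WordInstance",
    "Page",
    "assign_cell",
    "find_word_instances",
    "tokenize_structure",
    "instance_count_matrix",
]

DEFAULT_CELL_SIZE = 15.0


@dataclasses.dataclass(frozen=True, order=True)
class PageKey:
    structure_id: str
    cell: tuple[int, int, int]


@dataclasses.dataclass(frozen=True)
class WordInstance:
    """One concrete occurrence of a word: matched atoms in canonical order."""

    word_id: str
    variant_id: str
    atoms: tuple[Atom, ...]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_ids(self) -> tuple[tuple[str, int, str, str], ...]:
        seen: list[tuple[str, int, str, str]] = []
        for a in self.atoms:
            if a.residue_id not in seen:
                seen.append(a.residue_id)
        return tuple(seen)


@dataclasses.dataclass
class Page:
    """One cube of a structure: its atoms and the word instances homed here."""

    key: PageKey
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    instances: dict[str, list[WordInstance]] = dataclasses.field(default_factory=dict)

    def instance_count(self, word_id: str) -> int:
        return len(self.instances.get(word_id, []))


def assign_cell(point, cell_size: float = DEFAULT_CELL_SIZE) -> tuple[int, int, int]:
    """Lattice cell of a point: floor(coordinate / cell_size) per axis.

    Cells are half-open boxes [c*s, (c+1)*s) anchored at the origin.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    p = np.asarray(point, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError(f"point must be a finite 3-vector, got {point!r}")
    return tuple(int(math.floor(x / cell_size)) for x in p)


def _residue_matches(res_name: str, pattern_res: str) -> bool:
    if pattern_res == WILDCARD:
        return res_name in STANDARD_RESIDUES
    return res_name == pattern_res


def _match_variant(
    variant: WordVariant,
    residues: list[tuple[tuple[str, int, str, str], dict[str, Atom]]],
    start: int,
) -> tuple[Atom, ...] | None:
    """Try to match a variant anchored at residue index ``start``."""
    span = variant.max_offset + 1
    if start + span > len(residues):
        return None
    window = residues[start : start + span]
    if span == 2:  # both residues in one chain, sequence-adjacent
        (c0, s0, i0, _), _ = window[0]
        (c1, s1, i1, _), _ = window[1]
        if c0 != c1:
            return None
        if not (s1 - s0 == 1 or (s1 == s0 and i1 != i0)):
            return None
    matched: list[Atom] = []
    for res_pat, atom_name, offset in variant.pattern:
        rid, atom_map = window[offset]
        if not _residue_matches(rid[3], res_pat):
            return None
        atom = atom_map.get(atom_name)
        if atom is None:
            return None
        matched.append(atom)
    return tuple(matched)


def find_word_instances(atoms: list[Atom], lexicon: Lexicon) -> list[WordInstance]:
    """Detect every word instance among ``atoms``, in residue order.

    Matching is purely by names: a variant matches when all its
    (residue, atom, offset) entries are present; missing atoms simply
    produce no instance. Two-residue variants require their residues to be
    consecutive in the same chain.
    """
    residues: list[tuple[tuple[str, int, str, str], dict[str, Atom]]] = []
    order: dict[tuple[str, int, str, str], int] = {}
    for atom in atoms:
        rid = atom.residue_id
        if rid not in order:
            order[rid] = len(residues)
            residues.append((rid, {}))
        residues[order[rid]][1].setdefault(atom.name, atom)

    instances: list[WordInstance] = []
    for start in range(len(residues)):
        for word in lexicon.words:
            for variant in word.variants:
                matched = _match_variant(variant, residues, start)
                if matched is not None:
                    instances.append(
                        WordInstance(
                            word_id=word.word_id,
                            variant_id=variant.variant_id,
                            atoms=matched,
                        )
                    )
    return instances


def tokenize_structure(
    structure: Structure,
    lexicon: Lexicon,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> list[Page]:
    """Partition a structure into pages and home each word instance.

    Every atom lands in exactly one page (its own cell); every instance is
    homed in the page of its centroid, which may differ from the cells of
    some of its atoms.
    """
    pages: dict[tuple[int, int, int], Page] = {}

    def page_for(cell: tuple[int, int, int]) -> Page:
        if cell not in pages:
            pages[cell] = Page(key=PageKey(structure.structure_id, cell))
        return pages[cell]

    for atom in structure.atoms:
        page_for(assign_cell(atom.coords, cell_size)).atoms.append(atom)

    for inst in find_word_instances(structure.atoms, lexicon):
        page = page_for(assign_cell(inst.centroid, cell_size))
        page.instances.setdefault(inst.word_id, []).append(inst)

    return [pages[c] for c in sorted(pages)]


def instance_count_matrix(pages: list[Page]) -> dict[str, int]:
    """Total instances per word over a set of pages."""
    totals: dict[str, int] = {}
    for page in pages:
        for word_id, insts in page.instances.items():
            totals[word_id] = totals.get(word_id, 0) + len(insts)
    return totals
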