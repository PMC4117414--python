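"""Build, serialize, and query the forward index and page database.

The forward index is a record-level inverted index: word -> page -> count.
It answers "which pages hold at least the required number of instances of
every query word", ordered so pages that only just satisfy the counts come
first — those admit the fewest correspondence permutations. The page
database keeps, per page, the atoms of the cube and every homed word
instance with its coordinates, ready to be aligned and returned.

The on-disk container is versioned JSON with the lexicon fingerprint
embedded, so an index can never be searched with a different lexicon than
it was built with.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from .lexicon import Lexicon
from .structure import Atom, EmptyStructureError, read_pdb
from .tokenizer import DEFAULT_CELL_SIZE, Page, PageKey, WordInstance, tokenize_structure

__all__ = [
    "FORMAT_VERSION",
    "ForwardIndex",
    "PageDatabase",
    "IndexError_",
    "IndexFormatError",
    "UnknownWordError",
    "build_index",
    "save_index",
    "load_index",
    "candidate_pages",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


class IndexError_(ValueError):
    """Invalid index build input."""


class IndexFormatError(ValueError):
    """Unreadable or incompatible on-disk index."""


class UnknownWordError(KeyError):
    """A required word_id is not part of the index's lexicon."""


@dataclasses.dataclass
class ForwardIndex:
    postings: dict[str, dict[PageKey, int]]
    lexicon_fingerprint: str
    cell_size: float
    word_ids: frozenset[str]


@dataclasses.dataclass
class PageDatabase:
    pages: dict[PageKey, Page]


def build_index(
    structure_paths: list[str | Path],
    lexicon: Lexicon,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> tuple[ForwardIndex, PageDatabase]:
    """Index a set of PDB files.

    Unreadable or empty structures are skipped with a warning so that a
    large build survives individual bad files; an entirely empty build is
    an error.
    """
    if not structure_paths:
        raise IndexError_("no structures given")
    postings: dict[str, dict[PageKey, int]] = {}
    pages: dict[PageKey, Page] = {}
    n_ok = 0
    for path in structure_paths:
        try:
            structure = read_pdb(path)
        except (OSError, EmptyStructureError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        n_ok += 1
        for page in tokenize_structure(structure, lexicon, cell_size):
            pages[page.key] = page
            for word_id, insts in page.instances.items():
                postings.setdefault(word_id, {})[page.key] = len(insts)
    if n_ok == 0:
        raise IndexError_("no structure could be parsed")
    index = ForwardIndex(
        postings=postings,
        lexicon_fingerprint=lexicon.fingerprint(),
        cell_size=cell_size,
        word_ids=frozenset(w.word_id for w in lexicon.words),
    )
    return index, PageDatabase(pages=pages)


def candidate_pages(
    index: ForwardIndex, required: dict[str, int]
) -> list[PageKey]:
    """Pages holding >= the required count of every required word.

    Ordered by surplus (total posted minus required instances) ascending —
    pages closest to the minimum word counts first — with ties broken
    lexicographically by (structure_id, cell) for determinism.
    """
    if not required:
        raise IndexError_("empty requirement")
    for word_id, count in required.items():
        if word_id not in index.word_ids:
            raise UnknownWordError(word_id)
        if count < 1:
            raise IndexError_(f"required count for {word_id} must be >= 1")

    result: dict[PageKey, int] | None = None
    for word_id, count in required.items():
        posted = index.postings.get(word_id, {})
        matching = {k: v - count for k, v in posted.items() if v >= count}
        if result is None:
            result = matching
        else:
            result = {k: result[k] + s for k, s in matching.items() if k in result}
        if not result:
            return []
    assert result is not None
    return sorted(result, key=lambda k: (result[k], k.structure_id, k.cell))


# ---------------------------------------------------------------- on-disk

def _atom_to_row(a: Atom) -> list:
    return [a.serial, a.name, a.alt_loc, a.res_name, a.chain_id,
            a.res_seq, a.i_code, a.coords[0], a.coords[1], a.coords[2], a.element]


def _atom_from_row(row: list) -> Atom:
    return Atom(serial=row[0], name=row[1], alt_loc=row[2], res_name=row[3],
                chain_id=row[4], res_seq=row[5], i_code=row[6],
                coords=(row[7], row[8], row[9]), element=row[10])


def save_index(index: ForwardIndex, pagedb: PageDatabase, path: str | Path) -> None:
    """Write index + page database as a single versioned JSON file."""
    doc = {
        "format_version": FORMAT_VERSION,
        "lexicon_fingerprint": index.lexicon_fingerprint,
        "cell_size": index.cell_size,
        "word_ids": sorted(index.word_ids),
        "pages": [
            {
                "structure_id": key.structure_id,
                "cell": list(key.cell),
                "atoms": [_atom_to_row(a) for a in page.atoms],
                "instances": {
                    word_id: [
                        {"variant_id": inst.variant_id,
                         "atoms": [_atom_to_row(a) for a in inst.atoms]}
                        for inst in insts
                    ]
                    for word_id, insts in page.instances.items()
                },
            }
            for key, page in sorted(pagedb.pages.items())
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_index(path: str | Path) -> tuple[ForwardIndex, PageDatabase]:
    """Load an index written by :func:`save_index`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexFormatError(f"{path} is not a readable index file: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise IndexFormatError(
            f"index format version {version} not supported (expected {FORMAT_VERSION})"
        )
    pages: dict[PageKey, Page] = {}
    postings: dict[str, dict[PageKey, int]] = {}
    for entry in doc["pages"]:
        key = PageKey(entry["structure_id"], tuple(entry["cell"]))
        page = Page(key=key, atoms=[_atom_from_row(r) for r in entry["atoms"]])
        for word_id, insts in entry["instances"].items():
            page.instances[word_id] = [
                WordInstance(
                    word_id=word_id,
                    variant_id=i["variant_id"],
                    atoms=tuple(_atom_from_row(r) for r in i["atoms"]),
                )
                for i in insts
            ]
            postings.setdefault(word_id, {})[key] = len(page.instances[word_id])
        pages[key] = page
    index = ForwardIndex(
        postings=postings,
        lexicon_fingerprint=doc["lexicon_fingerprint"],
        cell_size=doc["cell_size"],
        word_ids=frozenset(doc["word_ids"]),
    )
    return index, PageDatabase(pages=pages)
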