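"""The structural-word lexicon.

A *word* is a small connected chemical motif named by residue and atom
identity — the indexing unit of the search engine, analogous to a word in
text search. Each word is specified by one or more PDB fragment files
(variants); a word with several variants matches any of them (e.g. a
carboxylate word with an aspartate variant and a glutamate variant).
Matching is by residue name + atom name + residue adjacency, never by
geometry, so chemically identical but differently named motifs stay
distinguishable and cis/trans isomers do not.

The package ships a default 28-word set covering general-purpose protein
searches: an any-residue backbone word, a two-residue peptide-bond word,
shared chemical moieties (hydroxyl, carboxylate, carboxamide) and one or
more words per side chain such that every residue except glycine owns at
least one word unique to it.
"""

from __future__ import annotations

import dataclasses
import hashlib
from importlib import resources
from pathlib import Path

from .structure import read_pdb

__all__ = [
    "STANDARD_RESIDUES",
    "WILDCARD",
    "WordVariant",
    "WordTemplate",
    "Lexicon",
    "LexiconStats",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "lexicon_stats",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue-name wildcard used in template files: matches any standard residue.
WILDCARD = "ANY"


class LexiconError(ValueError):
    """Invalid lexicon directory, manifest, or template file."""


@dataclasses.dataclass(frozen=True)
class WordVariant:
    """One concrete residue/atom-name pattern of a word.

    ``pattern`` is an ordered list of (res_name, atom_name, residue_offset)
    triples; the order is the canonical atom order used for atom-for-atom
    correspondence during alignment. ``residue_offset`` is 0 for the
    variant's anchor residue and 1 for the following residue in words that
    span a peptide bond.
    """

    variant_id: str
    pattern: tuple[tuple[str, str, int], ...]

    @property
    def atom_count(self) -> int:
        return len(self.pattern)

    @property
    def res_names(self) -> frozenset[str]:
        return frozenset(rn for rn, _, _ in self.pattern)

    @property
    def max_offset(self) -> int:
        return max(off for _, _, off in self.pattern)

    def __post_init__(self) -> None:
        if len(set(self.pattern)) != len(self.pattern):
            raise LexiconError(
                f"variant {self.variant_id}: duplicate (residue, atom, offset) entry"
            )
        offsets = {off for _, _, off in self.pattern}
        if not offsets <= {0, 1}:
            raise LexiconError(
                f"variant {self.variant_id}: residue offsets must be 0 or 1, got {offsets}"
            )
        if 0 not in offsets:
            raise LexiconError(f"variant {self.variant_id}: no anchor-residue atom")


@dataclasses.dataclass(frozen=True)
class WordTemplate:
    word_id: str
    name: str
    variants: tuple[WordVariant, ...]

    @property
    def atom_count(self) -> int:
        return self.variants[0].atom_count

    @property
    def res_names(self) -> frozenset[str]:
        names: set[str] = set()
        for v in self.variants:
            names |= v.res_names
        return frozenset(names)

    def __post_init__(self) -> None:
        if not self.variants:
            raise LexiconError(f"word {self.word_id}: no variants")
        arities = {v.atom_count for v in self.variants}
        if len(arities) != 1:
            raise LexiconError(
                f"word {self.word_id}: variants disagree on atom count {sorted(arities)}"
            )
        patterns = [v.pattern for v in self.variants]
        if len(set(patterns)) != len(patterns):
            raise LexiconError(f"word {self.word_id}: duplicate variant patterns")


@dataclasses.dataclass(frozen=True)
class Lexicon:
    words: tuple[WordTemplate, ...]
    source_dir: str

    def __post_init__(self) -> None:
        ids = [w.word_id for w in self.words]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LexiconError(f"duplicate word_ids: {dupes}")

    def __getitem__(self, word_id: str) -> WordTemplate:
        for w in self.words:
            if w.word_id == word_id:
                return w
        raise KeyError(word_id)

    def __contains__(self, word_id: str) -> bool:
        return any(w.word_id == word_id for w in self.words)

    def __len__(self) -> int:
        return len(self.words)

    def fingerprint(self) -> str:
        """Stable hash of the full word/variant/pattern content."""
        h = hashlib.sha256()
        for w in self.words:
            h.update(w.word_id.encode())
            for v in w.variants:
                h.update(v.variant_id.encode())
                for triple in v.pattern:
                    h.update(repr(triple).encode())
        return h.hexdigest()


def _parse_variant_file(path: Path, variant_id: str) -> WordVariant:
    st = read_pdb(path)
    residue_ids = list(st.residues)
    if len(residue_ids) > 2:
        raise LexiconError(f"{path.name}: template spans more than two residues")
    anchor_seq = residue_ids[0][1]
    pattern = []
    for atom in st.atoms:
        offset = atom.res_seq - anchor_seq
        pattern.append((atom.res_name, atom.name, offset))
    return WordVariant(variant_id=variant_id, pattern=tuple(pattern))


def load_lexicon(template_dir: str | Path) -> Lexicon:
    """Load a lexicon from a directory of PDB templates plus a manifest.

    The manifest (``manifest.txt``) has one word per line:
    ``word_id <TAB> human name <TAB> comma-separated variant filenames``.
    Each template file's atom order defines the variant's canonical order.
    """
    template_dir = Path(template_dir)
    manifest = template_dir / "manifest.txt"
    if not manifest.is_file():
        raise LexiconError(f"no manifest.txt in {template_dir}")
    words: list[WordTemplate] = []
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            word_id, name, files = line.split("\t")
        except ValueError as exc:
            raise LexiconError(f"malformed manifest line: {line!r}") from exc
        variants = tuple(
            _parse_variant_file(template_dir / fname.strip(), Path(fname).stem)
            for fname in files.split(",")
        )
        words.append(WordTemplate(word_id=word_id, name=name, variants=variants))
    if not words:
        raise LexiconError(f"manifest in {template_dir} defines no words")
    return Lexicon(words=tuple(words), source_dir=str(template_dir))


def default_lexicon() -> Lexicon:
    """Load the 28-word default set shipped with the package."""
    root = resources.files("fragdex") / "data" / "lexicon"
    return load_lexicon(Path(str(root)))


@dataclasses.dataclass(frozen=True)
class LexiconStats:
    word_count: int
    min_atom_count: int
    max_atom_count: int
    #: residues matched by at least one variant
    covered_residues: frozenset[str]
    #: residue -> word_ids that match only that residue
    unique_words: dict[str, list[str]]


def lexicon_stats(lexicon: Lexicon) -> LexiconStats:
    """Summarise a lexicon: counts, size range, per-residue coverage."""
    covered: set[str] = set()
    unique: dict[str, list[str]] = {r: [] for r in sorted(STANDARD_RESIDUES)}
    for word in lexicon.words:
        names = word.res_names
        if WILDCARD in names:
            covered |= STANDARD_RESIDUES
        else:
            covered |= names & STANDARD_RESIDUES
            if len(names) == 1:
                (only,) = names
                if only in unique:
                    unique[only].append(word.word_id)
    return LexiconStats(
        word_count=len(lexicon.words),
        min_atom_count=min(w.atom_count for w in lexicon.words),
        max_atom_count=max(w.atom_count for w in lexicon.words),
        covered_residues=frozenset(covered),
        unique_words=unique,
    )
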