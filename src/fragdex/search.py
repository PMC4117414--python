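"""Query tokenization, correspondence enumeration, and streaming search.

A query is an atom selection that must tokenize into whole words — every
query atom in exactly one word instance. Search then walks the candidate
pages from the forward index (fewest surplus instances first), enumerates
every injective word-for-word assignment between query and page, computes
the Kabsch superposition of the assigned page atoms onto the query atoms,
and streams out each page whose residual RMSD is within the cutoff,
aligned into the query frame. Results are yielded as found — the caller
can render the first match while the rest of the database is still being
scanned — and stop at ``max_results`` (default 100) or an optional
wall-clock timeout.

Atom-for-atom correspondence inside a word follows the canonical template
atom order on both sides. Chemically symmetric orderings (e.g. swapping a
carboxylate's two oxygens) are not enumerated.
"""

from __future__ import annotations

import dataclasses
import itertools
import time
from typing import Iterator

import numpy as np

from .geometry import Superposition, apply_transform, superpose
from .index import ForwardIndex, PageDatabase, candidate_pages
from .lexicon import Lexicon
from .structure import Atom
from .tokenizer import Page, PageKey, WordInstance, find_word_instances

__all__ = [
    "Query",
    "QueryError",
    "LexiconMismatchError",
    "SearchResult",
    "SearchStream",
    "tokenize_query",
    "enumerate_assignments",
    "search",
]

DEFAULT_RMSD_CUTOFF = 1.0
DEFAULT_MAX_RESULTS = 100


class QueryError(ValueError):
    """Query atoms cannot be tokenized into whole words."""

    def __init__(self, uncovered: list[Atom]):
        self.uncovered = uncovered
        names = ", ".join(
            f"{a.chain_id}/{a.res_name}{a.res_seq}{a.i_code}:{a.name}" for a in uncovered
        )
        super().__init__(f"query atoms not coverable by any word: {names}")


class LexiconMismatchError(ValueError):
    """Query and index were built against different lexicons."""


@dataclasses.dataclass(frozen=True)
class Query:
    atoms: tuple[Atom, ...]
    instances: tuple[WordInstance, ...]
    required: dict[str, int]
    lexicon_fingerprint: str
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
    max_results: int = DEFAULT_MAX_RESULTS
    timeout: float | None = None

    def __post_init__(self) -> None:
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")
        if self.max_results < 1:
            raise ValueError("max_results must be >= 1")

    @property
    def coords(self) -> np.ndarray:
        """Query instance coordinates, concatenated in instance order."""
        return np.vstack([inst.coords for inst in self.instances])


def _select_cover(
    atoms: tuple[Atom, ...],
    instances: list[WordInstance],
    lexicon: Lexicon,
) -> tuple[WordInstance, ...]:
    """Exact cover of the query atoms by word instances, via backtracking.

    Candidate instances are preferred by word size (largest first), then
    manifest order, then residue order; words may overlap within a residue
    (CA sits in both the backbone word and side-chain linkers) so a greedy
    choice can dead-end and is undone.
    """
    atom_index = {id(a): i for i, a in enumerate(atoms)}
    word_rank = {w.word_id: r for r, w in enumerate(lexicon.words)}
    ranked = sorted(
        range(len(instances)),
        key=lambda i: (
            -instances[i].atoms.__len__(),
            word_rank[instances[i].word_id],
            min(atom_index[id(a)] for a in instances[i].atoms),
        ),
    )
    cover_sets = [frozenset(atom_index[id(a)] for a in instances[i].atoms) for i in ranked]
    n = len(atoms)
    all_atoms = frozenset(range(n))
    coverable = frozenset().union(*cover_sets) if cover_sets else frozenset()
    if coverable != all_atoms:
        raise QueryError([atoms[i] for i in sorted(all_atoms - coverable)])

    best_uncovered = [all_atoms]

    def backtrack(uncovered: frozenset[int], chosen: list[int]) -> list[int] | None:
        if not uncovered:
            return chosen
        if len(uncovered) < len(best_uncovered[0]):
            best_uncovered[0] = uncovered
        pivot = min(uncovered)
        for j, cov in enumerate(cover_sets):
            if pivot in cov and cov <= uncovered:
                found = backtrack(uncovered - cov, chosen + [j])
                if found is not None:
                    return found
        return None

    chosen = backtrack(all_atoms, [])
    if chosen is None:
        raise QueryError([atoms[i] for i in sorted(best_uncovered[0])])
    picked = [instances[ranked[j]] for j in sorted(chosen)]
    # stable order: by word manifest rank, then residue order in the query
    picked.sort(
        key=lambda inst: (
            word_rank[inst.word_id],
            min(atom_index[id(a)] for a in inst.atoms),
        )
    )
    return tuple(picked)


def tokenize_query(
    atoms: list[Atom],
    lexicon: Lexicon,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    max_results: int = DEFAULT_MAX_RESULTS,
    timeout: float | None = None,
) -> Query:
    """Tokenize an atom selection into a search query.

    All word instances among the atoms are detected with the same matcher
    used for indexing, then an exact cover is selected so every query atom
    belongs to exactly one instance. An atom selection that cannot be
    partitioned into whole words is rejected, naming the uncovered atoms.
    """
    if not atoms:
        raise QueryError([])
    atoms_t = tuple(atoms)
    instances = find_word_instances(list(atoms_t), lexicon)
    cover = _select_cover(atoms_t, instances, lexicon)
    required: dict[str, int] = {}
    for inst in cover:
        required[inst.word_id] = required.get(inst.word_id, 0) + 1
    return Query(
        atoms=atoms_t,
        instances=cover,
        required=required,
        lexicon_fingerprint=lexicon.fingerprint(),
        rmsd_cutoff=rmsd_cutoff,
        max_results=max_results,
        timeout=timeout,
    )


@dataclasses.dataclass(frozen=True)
class SearchResult:
    """One matched correspondence: the whole page aligned onto the query."""

    page: PageKey
    assignment: tuple[tuple[WordInstance, WordInstance], ...]
    superposition: Superposition
    aligned_atoms: tuple[Atom, ...]

    @property
    def rmsd(self) -> float:
        return self.superposition.rmsd

    @property
    def matched_residues(self) -> tuple[tuple[str, int, str, str], ...]:
        seen: list[tuple[str, int, str, str]] = []
        for _, page_inst in self.assignment:
            for rid in page_inst.residue_ids:
                if rid not in seen:
                    seen.append(rid)
        return tuple(seen)

    @property
    def aligned_matched_coords(self) -> np.ndarray:
        """Matched page atoms transformed into the query frame."""
        mobile = np.vstack([p.coords for _, p in self.assignment])
        return self.superposition.transform.apply(mobile)


def enumerate_assignments(
    query: Query, page: Page
) -> Iterator[tuple[tuple[WordInstance, WordInstance], ...]]:
    """Every injective mapping of query instances onto page instances.

    Per word, the k query instances map onto ordered selections of k of
    the page's n instances (n!/(n-k)! mappings); the full assignment is
    the product over the query's words. Page instances are taken in their
    stored residue order, so iteration is deterministic.
    """
    by_word: dict[str, list[WordInstance]] = {}
    for inst in query.instances:
        by_word.setdefault(inst.word_id, []).append(inst)
    word_ids = list(by_word)
    pools = [page.instances.get(w, []) for w in word_ids]
    per_word_choices = [
        itertools.permutations(pool, len(by_word[w]))
        for w, pool in zip(word_ids, pools)
    ]
    for combo in itertools.product(*per_word_choices):
        assignment: list[tuple[WordInstance, WordInstance]] = []
        for w, picks in zip(word_ids, combo):
            assignment.extend(zip(by_word[w], picks))
        yield tuple(assignment)


class SearchStream:
    """Iterator over search results with truncation bookkeeping.

    Attributes ``pages_visited``, ``results_yielded``, ``timed_out`` and
    ``truncated`` describe how far the scan got; ``truncated`` is set when
    the stream stopped early (result limit or timeout) rather than by
    exhausting the candidate pages.
    """

    def __init__(self, index: ForwardIndex, pagedb: PageDatabase, query: Query):
        if index.lexicon_fingerprint != query.lexicon_fingerprint:
            raise LexiconMismatchError(
                "query was tokenized with a different lexicon than the index"
            )
        self.index = index
        self.pagedb = pagedb
        self.query = query
        self.pages_visited = 0
        self.results_yielded = 0
        self.timed_out = False
        self.truncated = False

    def __iter__(self) -> Iterator[SearchResult]:
        query = self.query
        deadline = None if query.timeout is None else time.monotonic() + query.timeout
        target = query.coords
        for key in candidate_pages(self.index, query.required):
            page = self.pagedb.pages[key]
            self.pages_visited += 1
            for assignment in enumerate_assignments(query, page):
                if deadline is not None and time.monotonic() > deadline:
                    self.timed_out = True
                    self.truncated = True
                    return
                mobile = np.vstack([p.coords for _, p in assignment])
                sup = superpose(mobile, target)
                if sup.rmsd <= query.rmsd_cutoff:
                    yield self._build_result(page, assignment, sup)
                    self.results_yielded += 1
                    if self.results_yielded >= query.max_results:
                        self.truncated = True
                        return

    def _build_result(
        self,
        page: Page,
        assignment: tuple[tuple[WordInstance, WordInstance], ...],
        sup: Superposition,
    ) -> SearchResult:
        # page atoms plus any matched instance atoms stored outside the cube
        atoms = list(page.atoms)
        seen = {(a.residue_id, a.name) for a in atoms}
        for _, page_inst in assignment:
            for a in page_inst.atoms:
                if (a.residue_id, a.name) not in seen:
                    seen.add((a.residue_id, a.name))
                    atoms.append(a)
        aligned = tuple(apply_transform(sup.transform, atoms))
        return SearchResult(
            page=page.key, assignment=assignment, superposition=sup, aligned_atoms=aligned
        )


def search(index: ForwardIndex, pagedb: PageDatabase, query: Query) -> SearchStream:
    """Stream search results for a tokenized query against an index."""
    return SearchStream(index, pagedb, query)
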