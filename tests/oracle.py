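"""Index-free exhaustive search oracle.

Scans every page of every structure directly (no forward index, no
candidate ordering), enumerates word assignments with its own recursive
injection enumerator, and superposes with scipy's align_vectors instead
of the package's Kabsch — an independent route to the same answer.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from fragdex.search import Query
from fragdex.structure import read_pdb
from fragdex.tokenizer import Page, WordInstance, tokenize_structure


def scipy_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Optimal-superposition RMSD via scipy (rotation from align_vectors)."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    return float(rssd) / np.sqrt(len(mobile))


def _injections(k: int, pool: list[WordInstance]):
    """All ordered injective selections of k items from pool (recursive)."""
    if k == 0:
        yield []
        return
    for i, item in enumerate(pool):
        for rest in _injections(k - 1, pool[:i] + pool[i + 1 :]):
            yield [item] + rest


def assignment_key(query: Query, assignment) -> tuple:
    """Canonical identity of an assignment for multiset comparison."""
    q_pos = {id(inst): i for i, inst in enumerate(query.instances)}
    return tuple(
        sorted(
            (q_pos[id(q)], p.word_id, p.variant_id, p.residue_ids)
            for q, p in assignment
        )
    )


def oracle_assignments(query: Query, page: Page):
    by_word: dict[str, list[WordInstance]] = {}
    for inst in query.instances:
        by_word.setdefault(inst.word_id, []).append(inst)
    word_ids = list(by_word)

    def recurse(w_idx: int, acc):
        if w_idx == len(word_ids):
            yield list(acc)
            return
        w = word_ids[w_idx]
        q_insts = by_word[w]
        pool = page.instances.get(w, [])
        for picks in _injections(len(q_insts), pool):
            yield from recurse(w_idx + 1, acc + list(zip(q_insts, picks)))

    yield from recurse(0, [])


def oracle_search(structure_paths, lexicon, query: Query, cell_size: float = 15.0):
    """Exhaustive search over all pages: [(page_key, assignment_key, rmsd)]."""
    hits = []
    target = query.coords
    for path in structure_paths:
        structure = read_pdb(path)
        for page in tokenize_structure(structure, lexicon, cell_size):
            for assignment in oracle_assignments(query, page):
                mobile = np.vstack([p.coords for _, p in assignment])
                r = scipy_superpose_rmsd(mobile, target)
                if r <= query.rmsd_cutoff:
                    hits.append((page.key, assignment_key(query, assignment), round(r, 6)))
    return hits
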