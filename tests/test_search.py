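import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fragdex.fixtures import ideal_residue, word_query_atoms
from fragdex.index import build_index, candidate_pages
from fragdex.search import (
    LexiconMismatchError,
    QueryError,
    enumerate_assignments,
    search,
    tokenize_query,
)
from fragdex.structure import Structure, write_pdb
from fragdex.tokenizer import find_word_instances, tokenize_structure
from conftest import compact_chain
from oracle import assignment_key, oracle_search


def rigidly_move(atoms, seed=0, translation=(20.0, -5.0, 8.0)):
    R = Rotation.random(random_state=seed).as_matrix()
    t = np.asarray(translation)
    return [dataclasses.replace(a, coords=tuple(R @ np.asarray(a.coords) + t)) for a in atoms]


@pytest.fixture(scope="module")
def db(planted_db, lexicon):
    paths, manifest = planted_db
    index, pagedb = build_index(paths, lexicon)
    return paths, manifest, index, pagedb


# ------------------------------------------------------------- tokenize_query

def test_guanidinium_group_query(lexicon):
    q = tokenize_query(word_query_atoms("guanidinium", lexicon), lexicon)
    assert q.required == {"guanidinium": 1}
    assert q.rmsd_cutoff == 1.0 and q.max_results == 100


def test_two_peptide_bonds_query(lexicon):
    first = word_query_atoms("peptide_bond", lexicon)
    second = [
        dataclasses.replace(a, res_seq=a.res_seq + 20, coords=tuple(np.asarray(a.coords) + [12, 0, 0]))
        for a in word_query_atoms("peptide_bond", lexicon)
    ]
    q = tokenize_query(first + second, lexicon)
    assert q.required == {"peptide_bond": 2}
    assert len(q.instances) == 2


def test_stray_atom_rejected_by_name(lexicon):
    stray = [a for a in ideal_residue("PHE") if a.name == "CB"]
    with pytest.raises(QueryError, match="PHE1:CB"):
        tokenize_query(stray, lexicon)


def test_arginine_side_chain_coverable_but_whole_residue_not(lexicon):
    # arg_linker + guanidinium partition the side chain (with CA)
    side = [a for a in ideal_residue("ARG") if a.name not in ("N", "C", "O")]
    q = tokenize_query(side, lexicon)
    assert q.required == {"arg_linker": 1, "guanidinium": 1}
    # the whole residue is not an exact cover: CA sits in both the backbone
    # word and the linker, so queries stay restricted to motif groups
    with pytest.raises(QueryError):
        tokenize_query(ideal_residue("ARG"), lexicon)


def test_cover_backtracks_over_overlapping_words(lexicon):
    # ASP side chain: carboxylate (CG,OD1,OD2) + asp_linker (CA,CB); the
    # backbone word shares CA and must be passed over.
    atoms = [a for a in ideal_residue("ASP") if a.name in ("CA", "CB", "CG", "OD1", "OD2")]
    q = tokenize_query(atoms, lexicon)
    assert q.required == {"carboxylate": 1, "asp_linker": 1}


# ----------------------------------------------------- enumerate_assignments

def test_two_of_five_yields_twenty_assignments(lexicon):
    st = Structure("polyala", compact_chain(6))  # 5 peptide bonds in one page
    page = tokenize_structure(st, lexicon)[0]
    assert page.instance_count("peptide_bond") == 5
    first = word_query_atoms("peptide_bond", lexicon)
    second = [dataclasses.replace(a, res_seq=a.res_seq + 20,
                                  coords=tuple(np.asarray(a.coords) + [12, 0, 0]))
              for a in word_query_atoms("peptide_bond", lexicon)]
    q = tokenize_query(first + second, lexicon)
    assignments = list(enumerate_assignments(q, page))
    assert len(assignments) == 20  # ordered injections 5*4
    assert len({assignment_key(q, a) for a in assignments}) == 20


def test_cross_variant_assignments(lexicon, tmp_path):
    # both residues placed well inside one 15 Å cell
    atoms = [dataclasses.replace(a, coords=tuple(np.asarray(a.coords) + [6, 6, 6]))
             for a in ideal_residue("ASP", res_seq=1)]
    atoms += [dataclasses.replace(a, coords=tuple(np.asarray(a.coords) + [10, 6, 6]))
              for a in ideal_residue("GLU", res_seq=11)]
    pages = tokenize_structure(Structure("x", atoms), lexicon)
    (page,) = [p for p in pages if p.instance_count("carboxylate") == 2]
    q = tokenize_query(word_query_atoms("carboxylate", lexicon), lexicon)
    assignments = list(enumerate_assignments(q, page))
    assert len(assignments) == 2
    assert {a[0][1].variant_id for a in assignments} == {"carboxylate__ASP", "carboxylate__GLU"}


def test_absent_word_yields_no_assignments(lexicon):
    page = tokenize_structure(Structure("x", compact_chain(3)), lexicon)[0]
    q = tokenize_query(word_query_atoms("guanidinium", lexicon), lexicon)
    assert list(enumerate_assignments(q, page)) == []


# ------------------------------------------------------------------- search

def test_self_retrieval_is_exact(db, lexicon):
    paths, _, index, pagedb = db
    from fragdex.structure import read_pdb

    atoms = read_pdb(paths[0]).atoms
    inst = next(i for i in find_word_instances(atoms, lexicon) if i.word_id == "guanidinium")
    q = tokenize_query(list(inst.atoms), lexicon, rmsd_cutoff=0.1)
    results = list(search(index, pagedb, q))
    best = min(results, key=lambda r: r.rmsd)
    assert best.rmsd <= 1e-6
    assert best.page.structure_id == paths[0].stem
    assert np.allclose(best.superposition.transform.rotation, np.eye(3), atol=1e-5)
    assert np.allclose(best.superposition.transform.translation, 0.0, atol=1e-4)


def test_rigidly_moved_query_gives_identical_results(db, lexicon):
    _, _, index, pagedb = db
    base_atoms = word_query_atoms("guanidinium+carboxylate", lexicon)
    q1 = tokenize_query(base_atoms, lexicon, rmsd_cutoff=1.0, max_results=10**6)
    q2 = tokenize_query(rigidly_move(base_atoms, seed=5), lexicon, rmsd_cutoff=1.0, max_results=10**6)
    r1 = sorted((assignment_key(q1, r.assignment), round(r.rmsd, 6)) for r in search(index, pagedb, q1))
    r2 = sorted((assignment_key(q2, r.assignment), round(r.rmsd, 6)) for r in search(index, pagedb, q2))
    assert [k for k, _ in r1] == [k for k, _ in r2]
    assert np.allclose([v for _, v in r1], [v for _, v in r2], atol=1e-6)


def test_planted_pairs_found_and_match_oracle(db, lexicon):
    paths, manifest, index, pagedb = db
    q = tokenize_query(word_query_atoms("guanidinium+carboxylate", lexicon),
                       lexicon, rmsd_cutoff=1.0, max_results=10**6)
    results = list(search(index, pagedb, q))
    planted = sum(1 for s in manifest["structures"] for p in s["planted"]
                  if p["word_spec"] == "guanidinium+carboxylate")
    assert len(results) == planted == 3
    got = sorted((r.page, assignment_key(q, r.assignment), round(r.rmsd, 6)) for r in results)
    expected = sorted(oracle_search(paths, lexicon, q))
    assert got == expected


def test_cutoff_soundness_and_remeasurement(db, lexicon):
    _, _, index, pagedb = db
    q = tokenize_query(word_query_atoms("backbone", lexicon), lexicon,
                       rmsd_cutoff=0.8, max_results=10**6)
    results = list(search(index, pagedb, q))
    assert results
    for r in results:
        assert r.rmsd <= 0.8
        remeasured = np.sqrt(np.mean(np.sum((r.aligned_matched_coords - q.coords) ** 2, axis=1)))
        assert remeasured == pytest.approx(r.rmsd, abs=1e-6)
        # the matched atoms are present among the aligned result atoms
        aligned_by_key = {(a.residue_id, a.name): a.coords for a in r.aligned_atoms}
        for (_, page_inst), coords in zip(r.assignment, [None] * len(r.assignment)):
            for atom in page_inst.atoms:
                assert (atom.residue_id, atom.name) in aligned_by_key


def test_cutoff_monotonicity(db, lexicon):
    _, _, index, pagedb = db
    base = word_query_atoms("peptide_bond", lexicon)
    keysets = []
    for cutoff in (0.3, 0.6, 1.0):
        q = tokenize_query(base, lexicon, rmsd_cutoff=cutoff, max_results=10**6)
        keysets.append({(r.page, assignment_key(q, r.assignment)) for r in search(index, pagedb, q)})
    assert keysets[0] <= keysets[1] <= keysets[2]


def test_limit_returns_prefix_of_unlimited_stream(db, lexicon):
    _, _, index, pagedb = db
    base = word_query_atoms("backbone", lexicon)
    q_all = tokenize_query(base, lexicon, rmsd_cutoff=1.0, max_results=10**6)
    all_results = [(r.page, assignment_key(q_all, r.assignment)) for r in search(index, pagedb, q_all)]
    assert len(all_results) > 3
    q_k = tokenize_query(base, lexicon, rmsd_cutoff=1.0, max_results=3)
    stream = search(index, pagedb, q_k)
    limited = [(r.page, assignment_key(q_k, r.assignment)) for r in stream]
    assert limited == all_results[:3]
    assert stream.truncated and not stream.timed_out


def test_first_result_streams_before_scan_completes(db, lexicon):
    _, _, index, pagedb = db
    q = tokenize_query(word_query_atoms("guanidinium", lexicon), lexicon,
                       rmsd_cutoff=1.0, max_results=10**6)
    n_candidates = len(candidate_pages(index, q.required))
    assert n_candidates >= 3
    stream = search(index, pagedb, q)
    next(iter(stream))
    assert stream.pages_visited < n_candidates


def test_timeout_truncates_cleanly(db, lexicon):
    _, _, index, pagedb = db
    q = tokenize_query(word_query_atoms("backbone", lexicon), lexicon,
                       rmsd_cutoff=1.0, max_results=10**6, timeout=0.0)
    stream = search(index, pagedb, q)
    results = list(stream)
    assert results == []
    assert stream.timed_out and stream.truncated


def test_lexicon_fingerprint_mismatch_rejected(db, lexicon):
    _, _, index, pagedb = db
    q = tokenize_query(word_query_atoms("guanidinium", lexicon), lexicon)
    q_bad = dataclasses.replace(q, lexicon_fingerprint="deadbeef")
    with pytest.raises(LexiconMismatchError):
        search(index, pagedb, q_bad)
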