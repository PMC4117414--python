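# fragdex

A real-time, all-atom substructure search engine for protein structures.

Protein designers, modellers, and structural biologists often want to ask
"where else in known structures does *this exact arrangement of atoms*
occur?" — a salt bridge, a metal-coordinating pair of side chains, a
backbone fragment with particular torsions. Whole-fold comparison tools
answer a different question, and exhaustive all-atom scans are too slow
for an interactive search-and-refine workflow. fragdex answers the atomic
question quickly by borrowing the architecture of a text search engine:

- **Pages.** Each structure is partitioned into non-overlapping
  15 Å × 15 Å × 15 Å cubes, the unit of retrieval. Queries cannot span
  pages; in exchange, no duplicate-elimination step is ever needed.
- **Words.** Each page is tokenized into small connected chemical motifs
  (2–9 heavy atoms) identified purely by residue/atom names and residue
  adjacency — a hydroxyl, a carboxylate, a guanidinium, a backbone unit, a
  peptide bond, an indole ring… A bundled 28-word lexicon covers
  general-purpose protein searches; every residue except glycine has at
  least one word unique to it, so searches can be residue-specific.
- **Forward index.** A record-level inverted index maps each word to the
  pages containing it, with per-page counts. A query is tokenized into
  words, and only pages holding at least the required count of every query
  word are examined — ordered so pages that only just meet the counts
  (fewest correspondence permutations) come first.
- **Alignment filter.** Within each candidate page, every injective
  word-to-word assignment defines an exact atom-for-atom correspondence.
  The Kabsch algorithm gives the closed-form proper rotation **R** and
  translation **t** minimising
  RMSD = sqrt((1/n) Σᵢ ‖R xᵢ + t − yᵢ‖²)
  between the page atoms xᵢ and query atoms yᵢ. Every assignment within
  the RMSD cutoff (default 1.0 Å) is returned as a separate result: the
  whole page, rigidly aligned into the query frame.
- **Streaming.** Results are yielded as they are found, and the scan stops
  at the requested result limit (default 100) or an optional timeout.

A synthetic-fixture generator plants ideal-geometry motifs (from the
chemical component dictionary bundled with biotite) at controlled noise
levels into small PDB files, so the entire engine is testable — including
against an index-free exhaustive-search oracle — without downloading any
structure.

## Worked example

Generate three synthetic structures each containing one exact
arginine–aspartate salt bridge (plus a distorted decoy residue), index
them, and search with the ideal salt-bridge fragment:

```
$ fragdex fixtures --seed 21 --out fx --spec spec.json
3 structures written to fx
$ fragdex build --structures fx --out db.fragdex
$ fragdex search --index db.fragdex --query query.pdb --rmsd 1.0 \
    --out-dir results --jsonl results.jsonl
3 results written to results
$ cat results.jsonl
{"structure_id": "fx000", "cell": [2, 0, 0], "rmsd": 0.000416, "matched_residues": ["A/11//ASP", "A/1//ARG"]}
{"structure_id": "fx001", "cell": [0, 1, 0], "rmsd": 0.000386, "matched_residues": ["A/11//ASP", "A/1//ARG"]}
{"structure_id": "fx002", "cell": [2, 2, 2], "rmsd": 0.000423, "matched_residues": ["A/11//ASP", "A/1//ARG"]}
```

All three planted bridges are retrieved, one per page, each naming the
source structure, its 15 Å cell, and the matched residues. The RMSD of
≈ 0.0004 Å is the PDB coordinate-precision floor (coordinates are written
to 3 decimals), i.e. an exact geometric match. Each `results/result_*.pdb`
holds the full aligned page with `REMARK` lines carrying the provenance
and RMSD; the query here was written with
`fragdex.fixtures.word_query_atoms("guanidinium+carboxylate", lexicon)`.

`fragdex stats` summarises the bundled lexicon:

```
words: 28
atom count range: 2-9
residues covered: 20/20
residues without a unique word: GLY
```

The library API (`fragdex.build_index`, `fragdex.tokenize_query`,
`fragdex.search`, …) exposes the same pipeline in-process; `search`
returns a stream that yields aligned results incrementally.

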