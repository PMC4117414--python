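# Methods

## The search model

fragdex treats structural search the way a text engine treats document
retrieval. Three representational choices define the model, and all three
trade recall for speed in a way the user should understand:

**Pages.** Structures are partitioned into cubes of `cell_size` = 15 Å
(configurable at index build time), on a lattice anchored at the absolute
coordinate origin of each file's frame, with half-open cells
`[c·s, (c+1)·s)` per axis. The anchoring is a design choice — any fixed
lattice is equally defensible — made for determinism: the same file always
produces the same pages, independent of what else is indexed. Pages do not
overlap, so a motif whose parts fall in different cubes can never be
returned as one result. That lost recall is accepted in exchange for never
needing duplicate elimination: a correspondence exists in exactly one page.
The 15 Å scale assumes larger patterns of interest decompose into bridging
local interactions below that length.

**Words.** A word is an ordered list of (residue name, atom name, residue
offset) triples — 2 to 9 heavy atoms in the default lexicon — matched
purely by names and residue adjacency, never by geometry or element
graphs. Consequences: chemically identical motifs with different naming
(phenylalanine's ring carbons vs its Cα–Cβ–Cγ linker) are deliberately
distinguishable, and cis/trans isomers are deliberately *not*. A word may
have several variants of equal arity (the carboxylate word has an
aspartate and a glutamate variant); correspondence across variants is
positional in the canonical template atom order. Two-residue words
(the peptide bond) require their residues to be sequence-adjacent in one
chain: residue numbers differing by 1, or equal numbers with different
insertion codes. Hydrogens are excluded throughout; word sizes are
heavy-atom counts.

**Instances and homing.** Every residue (and consecutive pair) is tested
against every variant; an instance exists iff all pattern atoms are
present by name — incomplete side chains simply contribute nothing, no
imputation. Each instance is homed in the page containing its *centroid*,
keeping boundary-straddling instances whole (their atom coordinates are
stored with the instance, so search never needs cross-page lookups) while
preserving the partition of atoms into pages.

## The default lexicon

The bundled set has 28 words sized 2 (hydroxyl) to 9 (indole), chosen to
satisfy a small set of coverage principles: an any-residue backbone word
(N, CA, C, O) for geometrically precise backbone search; a two-residue
peptide-bond word (CA, C, O | N, CA); shared chemical moieties as
multi-variant words (hydroxyl = Ser/Thr/Tyr, carboxylate = Asp/Glu,
carboxamide = Asn/Gln); important moieties isolated as their own words
(imidazole, guanidinium, phenyl, indole); long flexible side chains
(lysine, methionine, arginine) split into two words each so partial
matches remain expressible; and per-residue linker/branch words so that
every residue except glycine owns at least one word unique to it, making
residue-restricted searches possible. Glycine is reachable only through
the shared backbone and peptide-bond words. The lexicon is data, not code:
a directory of PDB fragment files plus a one-line-per-word manifest, and
`load_lexicon` accepts any directory in the same layout. An index records
a SHA-256 fingerprint of its lexicon and refuses queries tokenized against
a different one.

## Query tokenization

A query must parse into whole words — every atom in exactly one instance.
Because words legitimately overlap within a residue (CA belongs to the
backbone word *and* to side-chain linker words), cover selection is a
backtracking exact-cover search, preferring larger words, then manifest
order, then residue order; ties resolve deterministically. Atom sets
admitting no exact cover (e.g. a complete arginine including backbone:
CA cannot be in both words) are rejected with the uncoverable atoms named.
This is the engine's "searches are groups of chemical motifs, not groups
of atoms" restriction surfacing at the API.

## Candidate ordering, enumeration, alignment

Pages qualify when they hold at least the required count of every query
word. Candidates are ordered by surplus — Σ over words of (posted −
required) — ascending, so pages that barely qualify, and hence admit the
fewest assignments, are examined first; ties break lexicographically by
(structure id, cell). Within a page, every injective per-word mapping of
query instances onto page instances is enumerated (k query instances
against n page instances give n!/(n−k)! ordered selections, multiplied
across words). Each assignment fixes an exact atom-for-atom
correspondence; the Kabsch superposition of page atoms onto query atoms is
computed in closed form via SVD with the determinant-correction branch, so
a reflection is never returned and chirality is always respected. RMSD is
measured over the matched word atoms only — never the whole page — and
results at or below the cutoff are streamed immediately, each carrying the
entire page rigidly mapped into the query frame (plus any matched atoms
stored in neighbouring cubes). Results are not re-sorted by RMSD: global
sorting would forfeit streaming, so the delivery order is candidate order.
Chemically symmetric atom orderings within a word (carboxylate OD1/OD2)
are not enumerated — matching is by named atoms, and enumerating
symmetries would square the permutation space; a symmetric match therefore
scores as the named correspondence dictates. Known limitation.

Two-point words make the superposition degenerate (any rotation carrying
one segment onto the other is optimal); the SVD solution remains a
minimiser and the RMSD value is unique, so 2-atom-word queries are legal.
`kabsch()` itself keeps the conventional n ≥ 3 contract; the relaxed
`superpose()` core is what search uses.

## Persistence

The on-disk index is a single versioned JSON document (format version,
lexicon fingerprint, cell size, pages with atoms and instances).
Coordinates round-trip exactly (shortest-repr doubles). Version and
fingerprint mismatches are hard errors; truncated files fail cleanly.
Unparseable structure files are skipped with a warning during builds so a
large build survives bad inputs.

## The synthetic-fixture generator

`fragdex.fixtures` emulates the one thing the engine cares about:
known-geometry motif instances at known locations. Ideal residue geometry
comes from the chemical component dictionary bundled with biotite (heavy
atoms, OXT stripped). A planted motif spec ("guanidinium+carboxylate")
is laid out canonically — successive words offset 6 Å apart, two-residue
words 3.8 Å — rigidly rotated and placed wholly inside one randomly chosen
15 Å cell, then perturbed with isotropic Gaussian noise of per-component
sigma (so per-atom displacement norms have RMS σ√3). Decoy residues are
re-noised until every word instance they contain exceeds 1.5 Å RMSD from
ideal geometry, guaranteeing they sit beyond the 1.0 Å default cutoff.
Everything derives from one seeded generator: identical specs produce
byte-identical files.

What the generator does *not* emulate: realistic backbone dihedrals,
packing, crystallographic disorder, chain topology beyond local sequence
adjacency, or inter-chain contacts. Tests passing on fixtures therefore
demonstrate the engine's retrieval logic — tokenization, indexing,
enumeration, alignment, filtering, streaming — not its scientific yield on
real crystal structures, which depends on the database indexed.

## Verification strategy and problem sizes

The strongest check is dual-route: every indexed search on fixture
databases is compared, as a multiset of (page, assignment, RMSD), against
an index-free exhaustive scan that uses its own recursive injection
enumerator and scipy's `Rotation.align_vectors` instead of the package's
Kabsch. The shipped acceptance run uses five seeded databases of 10
structures (~15 residues each), four query motifs, and cutoffs
0.3/0.6/1.0 Å — small enough to re-run in seconds, large enough that the
index, the candidate predicate, the ordering, and the enumeration are all
load-bearing. Self-retrieval (a motif cut verbatim from an indexed file)
must return RMSD ≤ 1e−6 with an identity alignment, and must be invariant
under rigid transformation of the query. Kabsch is additionally checked
against a 1,000-random-rotation oracle, a Nelder–Mead rotation-space
minimiser, scipy, and a mirror-image positivity test.

## Degenerate inputs and numerical choices

Collinear point sets superpose with an arbitrary rotation about the line
(any minimiser accepted). Orthonormality of rotations is enforced at
1e−6; RMSD equality assertions use 1e−6 Å; coordinate round-trips through
PDB are exact to the format's 3 decimals. Alternate locations keep only
"" or "A"; only the first MODEL of multi-model files is read (indexing an
NMR ensemble as one structure would double-count motifs). Timeouts are
wall-clock, checked between assignments so an in-flight result is never
torn; timeout truncation is flagged on the stream, not raised.
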