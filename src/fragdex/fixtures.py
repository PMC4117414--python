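"""Synthetic PDB fixtures with planted, geometry-controlled motifs.

Every module of the engine can be exercised without downloading a single
real structure: this generator writes small PDB files containing rigidly
placed ideal-geometry residues that realise chosen lexicon words, plus
"decoy" residues whose word instances are deliberately distorted past any
tested RMSD cutoff. A JSON manifest records the ground truth (which word
was planted where, at what noise level) so tests can compute expected
search outcomes exactly.

A planted motif spec may join several words with "+" (e.g. the salt
bridge "guanidinium+carboxylate"); the words are laid out in a fixed
canonical arrangement and placed as one rigid unit inside a single page,
so the matching query — :func:`word_query_atoms` of the same spec — finds
every unperturbed copy at RMSD 0.

Ideal residue geometry comes from the chemical component dictionary
bundled with biotite; heavy atoms only, terminal OXT stripped. This is
sufficient for motif matching — it makes no attempt at realistic backbone
dihedrals or full folds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import biotite.structure.info as _binfo
import numpy as np

from .geometry import RigidTransform, superpose
from .lexicon import STANDARD_RESIDUES, Lexicon
from .structure import Atom, read_pdb, write_pdb
from .tokenizer import assign_cell, find_word_instances

__all__ = [
    "FixtureSpec",
    "ideal_residue",
    "make_residue",
    "word_query_atoms",
    "plant_recipe",
    "make_fixture_set",
]

#: decoy word instances are distorted until they exceed this RMSD vs ideal
DECOY_MIN_RMSD = 1.5

#: canonical displacement between successive words of a "+" motif group (Å)
_WORD_SPACING = np.array([0.0, 6.0, 0.0])


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """What to plant. ``planted_motifs`` entries are (word_spec, copies,
    perturbation_sigma); a word_spec may join several word_ids with "+" to
    plant them as one rigid group inside one page. Copies are distributed
    round-robin over the structures. ``decoy_residues`` adds distorted
    residues per structure."""

    seed: int
    n_structures: int
    planted_motifs: tuple[tuple[str, int, float], ...]
    decoy_residues: int = 0
    box_extent: float = 45.0
    cell_size: float = 15.0

    def __post_init__(self) -> None:
        if self.box_extent <= 0 or self.n_structures < 1:
            raise ValueError("box_extent must be positive and n_structures >= 1")
        for _, copies, sigma in self.planted_motifs:
            if sigma < 0 or copies < 1:
                raise ValueError("copies >= 1 and perturbation_sigma >= 0 required")


def _ideal_coords(res_name: str) -> tuple[list[str], np.ndarray]:
    if res_name not in STANDARD_RESIDUES:
        raise ValueError(f"unsupported residue {res_name!r}")
    r = _binfo.residue(res_name)
    keep = [
        i
        for i, (el, nm) in enumerate(zip(r.element, r.atom_name))
        if el not in ("H", "D") and nm != "OXT"
    ]
    names = [str(r.atom_name[i]) for i in keep]
    return names, np.asarray(r.coord[keep], dtype=float)


def make_residue(
    res_name: str,
    placement: RigidTransform,
    perturbation_sigma: float,
    rng: np.random.Generator,
    chain_id: str = "A",
    res_seq: int = 1,
) -> list[Atom]:
    """An ideal-geometry residue, rigidly placed, with isotropic Gaussian
    coordinate noise of the given per-component sigma (Å)."""
    names, coords = _ideal_coords(res_name)
    coords = placement.apply(coords)
    if perturbation_sigma > 0:
        coords = coords + rng.normal(0.0, perturbation_sigma, coords.shape)
    return [
        Atom(
            serial=i + 1,
            name=n,
            alt_loc="",
            res_name=res_name,
            chain_id=chain_id,
            res_seq=res_seq,
            i_code="",
            coords=(float(c[0]), float(c[1]), float(c[2])),
            element=n[0],
        )
        for i, (n, c) in enumerate(zip(names, coords))
    ]


def ideal_residue(res_name: str, chain_id: str = "A", res_seq: int = 1) -> list[Atom]:
    """Ideal-geometry residue at the identity placement, no noise."""
    return make_residue(
        res_name, RigidTransform.identity(), 0.0, np.random.default_rng(0), chain_id, res_seq
    )


def plant_recipe(word_id: str, lexicon: Lexicon) -> list[tuple[str, np.ndarray]]:
    """Residues (with relative offsets) realising a word's first variant.

    Wildcard-residue words are realised with alanine; the two residues of a
    peptide-bond word sit 3.8 Å apart, matching the bundled template.
    """
    variant = lexicon[word_id].variants[0]
    out: list[tuple[str, np.ndarray]] = []
    for offset in range(variant.max_offset + 1):
        res_names = {rn for rn, _, off in variant.pattern if off == offset}
        (rn,) = res_names
        res = "ALA" if rn == "ANY" else rn
        out.append((res, np.array([3.8 * offset, 0.0, 0.0])))
    return out


def _spec_layout(
    word_spec: str, lexicon: Lexicon
) -> list[tuple[str, str, np.ndarray, int]]:
    """Canonical layout of a (possibly "+"-joined) motif spec.

    Returns (word_id, res_name, shift, res_seq) per residue. Residues of a
    two-residue word get consecutive sequence numbers; different words are
    separated by 10 so no spurious sequence adjacency arises.
    """
    layout: list[tuple[str, str, np.ndarray, int]] = []
    seq = 1
    for w_idx, word_id in enumerate(word_spec.split("+")):
        recipe = plant_recipe(word_id, lexicon)
        for r_idx, (res_name, shift) in enumerate(recipe):
            layout.append((word_id, res_name, shift + w_idx * _WORD_SPACING, seq + r_idx))
        seq += 10
    return layout


def word_query_atoms(word_spec: str, lexicon: Lexicon) -> list[Atom]:
    """The atoms of a motif spec at its canonical ideal geometry — a
    ready-made query whose unperturbed planted copies score RMSD 0.

    Wildcard words get concrete (alanine) residues so the query tokenizes
    cleanly; for "+"-joined specs the words sit in the same canonical
    arrangement used by :func:`make_fixture_set`.
    """
    layout = _spec_layout(word_spec, lexicon)
    placed: dict[int, list[Atom]] = {}
    for word_id, res_name, shift, seq in layout:
        atoms = ideal_residue(res_name, res_seq=seq)
        placed[seq] = [
            dataclasses.replace(a, coords=tuple(np.asarray(a.coords) + shift)) for a in atoms
        ]
    out: list[Atom] = []
    for w_idx, word_id in enumerate(word_spec.split("+")):
        variant = lexicon[word_id].variants[0]
        base_seq = 1 + 10 * w_idx
        for _, atom_name, offset in variant.pattern:
            out.append(next(a for a in placed[base_seq + offset] if a.name == atom_name))
    return out


def _ideal_variant_coords(variant_id: str, lexicon: Lexicon) -> np.ndarray:
    path = Path(lexicon.source_dir) / f"{variant_id}.pdb"
    return np.array([a.coords for a in read_pdb(path).atoms])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def _place_layout(
    layout: list[tuple[str, str, np.ndarray, int]],
    cell: tuple[int, int, int],
    cell_size: float,
    sigma: float,
    rng: np.random.Generator,
    seq_base: int,
) -> list[Atom]:
    """Rigidly place a whole layout inside one cell (retrying rotations)."""
    center = (np.asarray(cell, dtype=float) + 0.5) * cell_size
    shifts = np.array([shift for _, _, shift, _ in layout])
    group_center = shifts.mean(axis=0)
    for _ in range(500):
        R = _random_rotation(rng)
        atoms: list[Atom] = []
        for _, res_name, shift, seq in layout:
            placement = RigidTransform(R, center + R @ (shift - group_center))
            atoms.extend(make_residue(res_name, placement, sigma, rng, "A", seq_base + seq))
        if all(assign_cell(a.coords, cell_size) == cell for a in atoms):
            return atoms
    raise RuntimeError(f"could not place group inside cell {cell}")


def make_fixture_set(spec: FixtureSpec, out_dir: str | Path, lexicon: Lexicon) -> dict:
    """Write ``spec.n_structures`` PDB files plus a ground-truth manifest.

    Returns the manifest (also written as ``manifest.json``): for every
    structure, the planted motif groups with their residues, home cell and
    noise sigma, plus the decoy residues. Deterministic for a given spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_cells = max(1, int(spec.box_extent // spec.cell_size))
    all_cells = [(i, j, k) for i in range(n_cells) for j in range(n_cells) for k in range(n_cells)]

    # round-robin distribution of planted copies over structures
    per_structure: list[list[tuple[str, float]]] = [[] for _ in range(spec.n_structures)]
    slot = 0
    for word_spec, copies, sigma in spec.planted_motifs:
        for _ in range(copies):
            per_structure[slot % spec.n_structures].append((word_spec, sigma))
            slot += 1

    manifest: dict = {"seed": spec.seed, "structures": []}
    decoy_res_pool = sorted(STANDARD_RESIDUES - {"GLY", "ALA"})
    for s_idx in range(spec.n_structures):
        sid = f"fx{s_idx:03d}"
        atoms: list[Atom] = []
        entry: dict = {"structure_id": sid, "file": f"{sid}.pdb", "planted": [], "decoys": []}
        cells = [all_cells[i] for i in rng.permutation(len(all_cells))]
        seq_base = 0
        for word_spec, sigma in per_structure[s_idx]:
            cell = cells.pop()
            layout = _spec_layout(word_spec, lexicon)
            placed = _place_layout(layout, cell, spec.cell_size, sigma, rng, seq_base)
            atoms.extend(placed)
            entry["planted"].append(
                {
                    "word_spec": word_spec,
                    "residues": sorted({f"{a.chain_id}/{a.res_seq}/{a.res_name}" for a in placed}),
                    "cell": list(cell),
                    "sigma": sigma,
                }
            )
            seq_base += 10 * len(word_spec.split("+")) + 10
        for _ in range(spec.decoy_residues):
            cell = cells.pop() if cells else tuple(int(v) for v in rng.integers(0, n_cells, 3))
            res_name = decoy_res_pool[int(rng.integers(len(decoy_res_pool)))]
            placed = _make_decoy(res_name, cell, spec, rng, seq_base + 1, lexicon)
            atoms.extend(placed)
            entry["decoys"].append({"residue": f"A/{seq_base + 1}/{res_name}", "cell": list(cell)})
            seq_base += 10
        write_pdb(atoms, [f"synthetic fixture {sid}"], out_dir / f"{sid}.pdb")
        manifest["structures"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _make_decoy(
    res_name: str,
    cell: tuple[int, int, int],
    spec: FixtureSpec,
    rng: np.random.Generator,
    res_seq: int,
    lexicon: Lexicon,
) -> list[Atom]:
    """A residue whose every word instance is distorted beyond DECOY_MIN_RMSD
    relative to ideal geometry, so it can never match an ideal-geometry query
    at the cutoffs under test."""
    layout = [("", res_name, np.zeros(3), 0)]
    sigma = 1.2
    for _ in range(100):
        atoms = _place_layout(layout, cell, spec.cell_size, sigma, rng, res_seq)
        ok = True
        for inst in find_word_instances(atoms, lexicon):
            ideal = _ideal_variant_coords(inst.variant_id, lexicon)
            if superpose(inst.coords, ideal).rmsd <= DECOY_MIN_RMSD:
                ok = False
                break
        if ok:
            return atoms
        sigma *= 1.3
    raise RuntimeError("could not distort decoy residue sufficiently")
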