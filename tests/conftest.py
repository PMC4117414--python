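import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from fragdex.fixtures import FixtureSpec, ideal_residue, make_fixture_set
from fragdex.lexicon import default_lexicon
from fragdex.structure import Atom, write_pdb


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def compact_chain(n: int, res_name: str = "ALA", spacing: float = 4.0) -> list[Atom]:
    """A chain of n sequence-consecutive ideal residues packed into one
    15 Å cube: residues sit on a 3x3x3 grid of anchor points inside the
    cube interior (geometry is irrelevant to name-based tokenization)."""
    assert n <= 27
    atoms: list[Atom] = []
    for i in range(n):
        anchor = np.array([2.5 + spacing * (i % 3), 2.5 + spacing * ((i // 3) % 3), 2.5 + spacing * (i // 9)])
        for a in ideal_residue(res_name, res_seq=i + 1):
            # residues are ~3 Å across; anchors keep all atoms within [0, 15)
            atoms.append(dataclasses.replace(a, coords=tuple(0.25 * np.asarray(a.coords) + anchor)))
    return atoms


@pytest.fixture(scope="session")
def polyala_path(tmp_path_factory):
    """A 10-residue poly-alanine packed into a single page."""
    path = tmp_path_factory.mktemp("polyala") / "polyala10.pdb"
    write_pdb(compact_chain(10), ["synthetic poly-ALA 10-mer"], path)
    return path


@pytest.fixture(scope="session")
def planted_db(tmp_path_factory, lexicon):
    """Small fixture database: 3 exact salt-bridge pairs, noisy peptide
    bonds, and decoys, across 4 structures."""
    out = tmp_path_factory.mktemp("planted")
    spec = FixtureSpec(
        seed=11,
        n_structures=4,
        planted_motifs=(
            ("guanidinium+carboxylate", 3, 0.0),
            ("peptide_bond", 2, 0.1),
            ("imidazole", 2, 0.0),
        ),
        decoy_residues=2,
    )
    manifest = make_fixture_set(spec, out, lexicon)
    paths = sorted(out.glob("*.pdb"))
    return paths, manifest
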