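"""Shared fixtures: a tiny hand-controlled reference and mutation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mirmod.io_formats import ReferenceSet
from mirmod.reference_db import build_canonical_db

BASES = "ACGT"
# deterministic "different base" for engineering mismatches
OTHER = {"A": "C", "C": "G", "G": "T", "T": "A"}


def different_base(*exclude: str) -> str:
    for b in BASES:
        if b not in exclude:
            return b
    raise ValueError("no base left")


def make_toy_ref(seed: int = 42, mature_span=(17, 40), hairpin_len: int = 80):
    """One 80-nt hairpin with a 23-nt mature at [17, 40), unique by construction.

    The mature is regenerated until position 11 carries an A (so an A->G
    edit can be planted at the position index the internal-modification
    examples use) and until it occurs exactly once in the hairpin.
    """
    rng = np.random.default_rng(seed)
    start, end = mature_span
    while True:
        hp = "".join(rng.choice(list(BASES), size=hairpin_len))
        mat = hp[start:end]
        if hp.count(mat) == 1 and mat[11] == "A":
            return ReferenceSet({"toy-mir-1": hp}, {"toy-miR-1-5p": (mat, "toy-mir-1")})


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceSet:
    return make_toy_ref()


@pytest.fixture(scope="session")
def toy_db(toy_ref):
    return build_canonical_db(toy_ref)


@pytest.fixture(scope="session")
def toy_locus(toy_db):
    return toy_db.loci["toy-miR-1-5p"]


@pytest.fixture(scope="session")
def paralogue_ref() -> ReferenceSet:
    """Two hairpins carrying an identical mature (a paralogue family)."""
    rng = np.random.default_rng(7)
    while True:
        mat = "".join(rng.choice(list(BASES), size=22))
        flanks = ["".join(rng.choice(list(BASES), size=n)) for n in (17, 21, 15, 23)]
        hp_a = flanks[0] + mat + flanks[1]
        hp_b = flanks[2] + mat + flanks[3]
        if hp_a.count(mat) == 1 and hp_b.count(mat) == 1:
            return ReferenceSet(
                {"par-mir-1a": hp_a, "par-mir-1b": hp_b},
                {
                    "par-miR-1a-5p": (mat, "par-mir-1a"),
                    "par-miR-1b-5p": (mat, "par-mir-1b"),
                },
            )
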