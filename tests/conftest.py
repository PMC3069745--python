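"""Shared fixtures: toy structures and alignments built at test time."""

import numpy as np
import pytest

from modelprep import PairAlignment, ToySpec, make_structure

# The published example alignment of a model carrying a six-residue
# insertion relative to the target (sequence-based alignment variant).
INSERTION_TARGET = "HCYKS------GIQVR"
INSERTION_MODEL = "HCVNSYQSNLDAIKIR"


@pytest.fixture
def insertion_alignment() -> PairAlignment:
    return PairAlignment(INSERTION_TARGET, INSERTION_MODEL)


@pytest.fixture
def helix_structure():
    """16-residue ideal helix matching the insertion alignment's model row."""
    return make_structure(ToySpec(INSERTION_MODEL.replace("-", "")))


@pytest.fixture
def small_helix():
    return make_structure(ToySpec("AVLKSE"))


def perfect_alignment(seq: str) -> PairAlignment:
    return PairAlignment(seq, seq)
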