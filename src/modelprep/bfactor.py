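"""Error-model B factors from sequence similarity and/or accessible area.

The replacement B factor encodes the expected coordinate error of each
atom: conserved (high-similarity) segments get low B, exposed (high-ASA)
atoms get high B.  Similarity enters per residue with a negative sign,
area per atom with a positive sign, and the combined values are shifted so
the minimum is exactly the floor (10 Å² by default) whenever it would fall
below it.  A constant shift is harmless downstream because structure
factors are normalized before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignments import PairAlignment
from .asa import AsaResult
from .errors import ModelPrepError
from .scoring import SimilarityProfile
from .structure import Chain, Structure

MIN_B_DEFAULT = 10.0

MODES = ("original", "similarity", "asa", "combined")


@dataclass(frozen=True)
class BfactorModel:
    """Parameters of the B-factor replacement.

    `similarity_factor` and `asa_factor` are quoted positive; the negative
    sign of the similarity term is applied internally.
    """

    mode: str = "original"
    similarity_factor: float = 80.0  # Å² per similarity unit
    asa_factor: float = 12.0         # Å² per Å² of accessible area
    min_b: float = MIN_B_DEFAULT

    def __post_init__(self):
        if self.mode not in MODES:
            raise ModelPrepError(f"unknown B-factor mode {self.mode!r}")
        if self.min_b <= 0:
            raise ModelPrepError("min_b must be positive")
        if self.asa_factor < 0:
            raise ModelPrepError("asa_factor must be non-negative")
        if not np.isfinite(self.similarity_factor) or not np.isfinite(self.asa_factor):
            raise ModelPrepError("factors must be finite")


def shift_to_minimum(b_values: Sequence[float],
                     min_b: float = MIN_B_DEFAULT) -> np.ndarray:
    """Shift all values by a constant so the minimum equals `min_b`.

    Applied only when the minimum falls below the floor; ordering and all
    pairwise differences are preserved exactly.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ModelPrepError("no B values to shift")
    low = b.min()
    if low < min_b:
        b = b + (min_b - low)
    return b


def _residue_scores(chain: Chain, alignment: PairAlignment,
                    profile: SimilarityProfile,
                    model_indices: list[int] | None) -> list[float]:
    if model_indices is None:
        model_indices = list(range(len(chain.residues)))
    if len(model_indices) != len(chain.residues):
        raise ModelPrepError("model indices do not match chain length")
    cols = alignment.model_columns()
    return [float(profile.smoothed_scores[cols[j]]) for j in model_indices]


def assign_bfactors(structure: Structure, model: BfactorModel,
                    profiles: dict[str, SimilarityProfile] | None = None,
                    alignments: dict[str, PairAlignment] | None = None,
                    asa: AsaResult | None = None,
                    model_indices: dict[str, list[int]] | None = None) -> Structure:
    """Replace protein-atom B factors according to the selected model.

    Similarity-based modes need a per-chain profile and alignment (one score
    per residue, shared by all its atoms); ASA-based modes need per-atom
    areas computed on the original structure.  Hetero atoms keep their
    original B in every mode.  The shift to the minimum is applied jointly
    over all protein atoms, so relative weights between chains survive.
    """
    if model.mode == "original":
        return structure
    use_sim = model.mode in ("similarity", "combined")
    use_asa = model.mode in ("asa", "combined")
    atoms = []
    raw = []
    for chain in structure.protein_chains():
        sim_scores: list[float] | None = None
        if use_sim:
            if (profiles is None or alignments is None
                    or chain.chain_id not in profiles):
                raise ModelPrepError(
                    f"chain {chain.chain_id} has no alignment; "
                    "similarity-based B factors unavailable")
            sim_scores = _residue_scores(
                chain, alignments[chain.chain_id], profiles[chain.chain_id],
                None if model_indices is None
                else model_indices.get(chain.chain_id))
        for i, res in enumerate(chain.residues):
            for atom in res.atoms:
                value = 0.0
                if use_sim:
                    value -= model.similarity_factor * sim_scores[i]
                if use_asa:
                    if asa is None:
                        raise ModelPrepError("ASA result required for this mode")
                    value += model.asa_factor * asa.area_of(atom)
                atoms.append(atom)
                raw.append(value)
    if not atoms:
        raise ModelPrepError("no protein atoms to assign B factors to")
    shifted = shift_to_minimum(raw, model.min_b)
    for atom, b in zip(atoms, shifted):
        atom.b = float(b)
    return structure
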