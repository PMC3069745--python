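"""Normalized substitution matrices and similarity profiles.

Raw substitution matrices (identity, PAM250, BLOSUM50, BLOSUM62) are put on
a common scale by an affine rescaling chosen so that the background-weighted
mean self-match score is 1.0 and the expected score of randomly paired
residues is 0.0; columns where one row carries a gap score a fixed -1.0.
Per-column scores are then optionally smoothed with a triangular moving
average of half-width W, which spreads the influence of substitutions and
indels onto neighbouring positions and damps alignment noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .alignments import GAP, PairAlignment
from .errors import ModelPrepError
from .residues import AA1

GAP_SCORE = -1.0

MATRIX_NAMES = ("identity", "PAM250", "BLOSUM50", "BLOSUM62")


@dataclass(frozen=True)
class NormalizedMatrix:
    """A residue-pair scoring table on the normalized similarity scale.

    Self-matches average 1.0 under the background frequencies, random pairs
    average 0.0 and a residue-vs-gap column scores `gap_score` (-1.0).
    Unknown residues ('X' or any unrecognized letter) score 0.0 against
    every residue.
    """

    name: str
    entries: np.ndarray  # 20 x 20, indexed by AA1 order
    gap_score: float = GAP_SCORE

    def __post_init__(self):
        if self.entries.shape != (20, 20):
            raise ModelPrepError("matrix must cover the 20 amino acids")
        if not np.allclose(self.entries, self.entries.T, atol=1e-12):
            raise ModelPrepError("matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        """Score one alignment column (residue letters or '-')."""
        if a == GAP or b == GAP:
            return self.gap_score
        ia = AA1.find(a)
        ib = AA1.find(b)
        if ia < 0 or ib < 0:  # 'X' and other unknowns are neutral
            return 0.0
        return float(self.entries[ia, ib])


def normalize_matrix(raw_matrix: Mapping[tuple[str, str], float],
                     background: np.ndarray | None = None,
                     name: str = "custom") -> NormalizedMatrix:
    """Affinely rescale a raw substitution table to the normalized scale.

    With background frequencies p, the rescaling is
    s'(a,b) = (s(a,b) - E_rand) / (E_match - E_rand) where
    E_rand = sum_ab p_a p_b s(a,b) and E_match = sum_a p_a s(a,a), so the
    mean self-match maps to 1.0 and the random expectation to 0.0.  The gap
    score is fixed at -1.0.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or abs(background.sum() - 1.0) > 1e-9:
        raise ModelPrepError("background frequencies must be 20 values summing to 1")
    table = np.empty((20, 20))
    for i, a in enumerate(AA1):
        for j, b in enumerate(AA1):
            try:
                table[i, j] = raw_matrix[a, b]
            except KeyError:
                try:
                    table[i, j] = raw_matrix[b, a]
                except KeyError:
                    raise ModelPrepError(
                        f"raw matrix lacks an entry for residue pair {a}/{b}")
    e_rand = float(background @ table @ background)
    e_match = float(background @ np.diag(table))
    if abs(e_match - e_rand) < 1e-12:
        raise ModelPrepError("matrix not normalizable")
    entries = (table - e_rand) / (e_match - e_rand)
    entries = (entries + entries.T) / 2.0  # keep symmetry exact
    return NormalizedMatrix(name=name, entries=entries)


def identity_matrix() -> NormalizedMatrix:
    """The binary residue/gap matrix: 1.0 identical, 0.0 otherwise, -1.0 gap."""
    return NormalizedMatrix(name="identity", entries=np.eye(20))


def load_matrix(name: str) -> NormalizedMatrix:
    """Load a built-in matrix by name and normalize it (uniform background)."""
    if name.lower() == "identity":
        return identity_matrix()
    canonical = {n.lower(): n for n in MATRIX_NAMES}.get(name.lower())
    if canonical is None:
        raise ModelPrepError(
            f"unknown matrix {name!r}; available: {', '.join(MATRIX_NAMES)}")
    raw = substitution_matrices.load(canonical)
    table = {(a, b): float(raw[a, b]) for a in AA1 for b in AA1}
    return normalize_matrix(table, name=canonical)


def score_alignment(alignment: PairAlignment,
                    matrix: NormalizedMatrix) -> np.ndarray:
    """Raw per-column similarity scores of an alignment."""
    return np.array([matrix.score(t, m) for t, m in
                     zip(alignment.target_row, alignment.model_row)])


def smooth_scores(raw: np.ndarray, window: int) -> np.ndarray:
    """Triangular moving average of half-width `window`.

    Weights fall linearly from W+1 at the centre to 1 at offset W; at the
    sequence ends the window truncates and the weights renormalize over the
    positions actually available.
    """
    if window < 0:
        raise ModelPrepError("averaging window must be non-negative")
    raw = np.asarray(raw, dtype=float)
    if window == 0 or raw.size == 0:
        return raw.copy()
    w = window + 1.0 - np.abs(np.arange(-window, window + 1))
    # full convolution then centred slice: robust when the window spans the
    # whole sequence (mode="same" would change the output length there)
    num = np.convolve(raw, w)[window:window + raw.size]
    den = np.convolve(np.ones_like(raw), w)[window:window + raw.size]
    return num / den


@dataclass(frozen=True)
class SimilarityProfile:
    """Raw and smoothed per-column similarity scores for one alignment."""

    raw_scores: np.ndarray
    smoothed_scores: np.ndarray
    window: int
    matrix_name: str

    @property
    def positions(self) -> int:
        return len(self.raw_scores)


def similarity_profile(alignment: PairAlignment, matrix: NormalizedMatrix,
                       window: int) -> SimilarityProfile:
    """Score an alignment and smooth the scores in one step."""
    raw = score_alignment(alignment, matrix)
    return SimilarityProfile(raw_scores=raw,
                             smoothed_scores=smooth_scores(raw, window),
                             window=window, matrix_name=matrix.name)
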