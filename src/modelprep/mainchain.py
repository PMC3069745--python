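"""Main-chain deletion: threshold-based residue removal and trace clean-up.

Residues are kept or deleted by comparing the smoothed similarity score at
their alignment column to a threshold.  Because of smoothing, residues
aligned to target gaps may survive (they are renamed GAP and numbered with
insertion codes) and residues surrounded by gaps may go even though they
align with a target residue.  The "variable" threshold reproduces the
empirical optimum of retaining as many residues as there are aligned
positions in the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import GAP, PairAlignment
from .errors import ModelPrepError
from .scoring import SimilarityProfile
from .structure import Chain

VARIABLE = "variable"


@dataclass
class DeletionPlan:
    """Keep/delete decision for every model residue (model-sequence order)."""

    keep: list[bool]
    threshold: float
    window: int
    n_aligned: int

    @property
    def n_kept(self) -> int:
        return sum(self.keep)


def _model_scores(profile: SimilarityProfile,
                  alignment: PairAlignment) -> np.ndarray:
    cols = alignment.model_columns()
    return profile.smoothed_scores[cols]


def plan_deletion(profile: SimilarityProfile, alignment: PairAlignment,
                  threshold: float) -> DeletionPlan:
    """Flag each model residue: kept iff its smoothed score >= threshold."""
    if profile.positions != alignment.positions:
        raise ModelPrepError("profile length does not match alignment")
    scores = _model_scores(profile, alignment)
    return DeletionPlan(keep=[bool(s >= threshold) for s in scores],
                        threshold=threshold, window=profile.window,
                        n_aligned=alignment.n_aligned)


def variable_threshold(profile: SimilarityProfile, alignment: PairAlignment,
                       n_aligned: int | None = None) -> float:
    """Threshold that retains as many residues as there are aligned columns.

    Returns the n_aligned-th largest smoothed score over model-residue
    columns, the largest t for which at least n_aligned residues score >= t.
    Ties are kept rather than split, so the kept count can exceed n_aligned
    only when scores tie exactly at the threshold.
    """
    if profile.positions != alignment.positions:
        raise ModelPrepError("profile length does not match alignment")
    if n_aligned is None:
        n_aligned = alignment.n_aligned
    scores = np.sort(_model_scores(profile, alignment))[::-1]
    if not 1 <= n_aligned <= scores.size:
        raise ModelPrepError(
            f"aligned-position count {n_aligned} outside 1..{scores.size}")
    return float(scores[n_aligned - 1])


def _runs(flags: list[bool]):
    """Yield (value, start, stop) runs over a boolean list."""
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            yield flags[start], start, i
            start = i


def polish_trace(plan: DeletionPlan, ss_mask: list[bool] | None = None,
                 min_fragment: int = 3, max_reinstate: int = 3) -> DeletionPlan:
    """Clean the trace: drop short kept fragments, reinstate short deletions.

    A contiguous kept run shorter than `min_fragment` is deleted.  A deleted
    run of length <= `max_reinstate` is reinstated when it is flanked by kept
    residues on both sides and every residue of the run lies in an annotated
    helix or sheet (`ss_mask`, per model residue).  Without annotations the
    reinstatement pass is a no-op.
    """
    keep = list(plan.keep)
    for value, start, stop in _runs(keep):
        if value and stop - start < min_fragment:
            keep[start:stop] = [False] * (stop - start)
    if ss_mask is not None:
        flags = list(keep)
        for value, start, stop in _runs(flags):
            if value or stop - start > max_reinstate:
                continue
            if start == 0 or stop == len(flags):
                continue  # not flanked on both sides
            if flags[start - 1] and flags[stop]:
                if all(ss_mask[i] for i in range(start, stop)):
                    keep[start:stop] = [True] * (stop - start)
    return DeletionPlan(keep=keep, threshold=plan.threshold,
                        window=plan.window, n_aligned=plan.n_aligned)


def ss_mask_for_chain(chain: Chain, ss_ranges) -> list[bool]:
    """Per-residue flag: residue lies inside a HELIX/SHEET annotation."""
    mask = [False] * len(chain.residues)
    ids = [r.res_id for r in chain.residues]
    for ss in ss_ranges:
        if ss.chain_id != chain.chain_id:
            continue
        try:
            i0 = ids.index(ss.start)
            i1 = ids.index(ss.end)
        except ValueError:
            continue
        for i in range(min(i0, i1), max(i0, i1) + 1):
            mask[i] = True
    return mask


def apply_deletion(chain: Chain, plan: DeletionPlan) -> list[int]:
    """Remove flagged residues in place; returns kept model-residue indices."""
    if len(plan.keep) != len(chain.residues):
        raise ModelPrepError("deletion plan does not match chain length")
    kept = [i for i, k in enumerate(plan.keep) if k]
    if not kept:
        raise ModelPrepError(
            f"all residues of chain {chain.chain_id} deleted; lower threshold")
    chain.residues = [chain.residues[i] for i in kept]
    return kept


def renumber_to_target(chain: Chain, alignment: PairAlignment,
                       kept_indices: list[int] | None = None) -> Chain:
    """Renumber kept residues to target numbering; gap survivors become GAP.

    A residue aligned with a target residue takes that residue's 1-based
    target-sequence position.  A kept residue aligned with a target gap is
    renamed GAP and numbered with the last preceding target number plus
    insertion codes A, B, C, ... in chain order.
    """
    if kept_indices is None:
        kept_indices = list(range(len(chain.residues)))
    if len(kept_indices) != len(chain.residues):
        raise ModelPrepError("kept indices do not match chain length")
    cols = alignment.model_columns()
    numbers = alignment.target_numbers()
    last_number = 0
    icode_pos = 0
    for res, j in zip(chain.residues, kept_indices):
        col = cols[j]
        number = numbers[col]
        if number is not None:
            res.seqnum = number
            res.icode = ""
            last_number = number
            icode_pos = 0
        else:
            if icode_pos >= 26:
                raise ModelPrepError(
                    "more than 26 consecutive gap-aligned residues; "
                    "insertion codes exhausted")
            res.name = "GAP"
            res.seqnum = last_number
            res.icode = chr(ord("A") + icode_pos)
            icode_pos += 1
    return chain
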