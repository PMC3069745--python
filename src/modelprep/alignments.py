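"""Pairwise alignment container and readers (aligned FASTA / CLUSTAL).

An alignment pairs the target sequence (the protein to be solved) with the
model sequence (the homologue whose structure is edited).  Multiple sequence
alignments are reduced to a pairwise projection of the target and model rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .errors import ModelPrepError

GAP = "-"
_GAP_CHARS = "-."


@dataclass(frozen=True)
class PairAlignment:
    """A gapped pairwise alignment of target and model sequences.

    Rows use one-letter amino-acid codes plus 'X' for unknown residues and
    '-' for gaps; no column may be gapped in both rows.
    """

    target_row: str
    model_row: str

    def __post_init__(self):
        if len(self.target_row) != len(self.model_row):
            raise ModelPrepError(
                "alignment rows differ in length: "
                f"{len(self.target_row)} vs {len(self.model_row)}")
        if len(self.target_row) == 0:
            raise ModelPrepError("empty alignment")
        for i, (t, m) in enumerate(zip(self.target_row, self.model_row)):
            if t == GAP and m == GAP:
                raise ModelPrepError(f"column {i} is gapped in both rows")

    @property
    def positions(self) -> int:
        """Number of alignment columns."""
        return len(self.target_row)

    @property
    def n_aligned(self) -> int:
        """Columns carrying a residue on both rows."""
        return sum(t != GAP and m != GAP
                   for t, m in zip(self.target_row, self.model_row))

    @property
    def target_sequence(self) -> str:
        return self.target_row.replace(GAP, "")

    @property
    def model_sequence(self) -> str:
        return self.model_row.replace(GAP, "")

    def model_columns(self) -> list[int]:
        """Column index of each model residue, in model-sequence order."""
        return [i for i, m in enumerate(self.model_row) if m != GAP]

    def target_numbers(self) -> list[int | None]:
        """Per column: 1-based target-sequence position, or None at gaps."""
        out: list[int | None] = []
        n = 0
        for t in self.target_row:
            if t == GAP:
                out.append(None)
            else:
                n += 1
                out.append(n)
        return out


def _clean_row(seq: str) -> str:
    out = []
    for ch in seq.upper():
        out.append(GAP if ch in _GAP_CHARS else ch)
    return "".join(out)


def read_alignment_rows(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA or CLUSTAL file as (name, gapped row) pairs."""
    path = Path(path)
    last_err = None
    for fmt in ("fasta", "clustal"):
        try:
            msa = AlignIO.read(str(path), fmt)
            return [(rec.id, _clean_row(str(rec.seq))) for rec in msa]
        except Exception as exc:  # try the next format
            last_err = exc
    raise ModelPrepError(
        f"cannot read alignment {path} as aligned FASTA or CLUSTAL: {last_err}")


def project_pair(rows: list[tuple[str, str]],
                 target_name: str | None = None,
                 model_name: str | None = None,
                 model_sequence: str | None = None) -> PairAlignment:
    """Reduce a (possibly multiple) alignment to a target/model pair.

    The target row is the first row unless `target_name` selects another.
    The model row is selected by `model_name`, or by ungapped identity with
    `model_sequence`, or defaults to the second row.  Columns gapped in both
    projected rows are dropped.
    """
    if not rows:
        raise ModelPrepError("alignment has no rows")
    if target_name is not None:
        matches = [r for r in rows if r[0] == target_name]
        if not matches:
            raise ModelPrepError(f"no alignment row named {target_name!r}")
        target = matches[0]
    else:
        target = rows[0]
    candidates = [r for r in rows if r is not target]
    if not candidates:
        raise ModelPrepError("alignment needs at least two rows")
    if model_name is not None:
        matches = [r for r in candidates if r[0] == model_name]
        if not matches:
            raise ModelPrepError(f"no alignment row named {model_name!r}")
        model = matches[0]
    elif model_sequence is not None:
        matches = [r for r in candidates
                   if r[1].replace(GAP, "") == model_sequence]
        if not matches:
            raise ModelPrepError(
                "no alignment row matches the chain sequence")
        model = matches[0]
    else:
        model = candidates[0]
    t_row, m_row = [], []
    for t, m in zip(target[1], model[1]):
        if t == GAP and m == GAP:
            continue
        t_row.append(t)
        m_row.append(m)
    return PairAlignment("".join(t_row), "".join(m_row))
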