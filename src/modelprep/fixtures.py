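"""Deterministic toy proteins and alignments for exercising every stage.

Structures are built from ideal internal coordinates (helix or extended
backbone, idealized side chains); they carry correct topology and chirality
but make no energetic claims.  Alignments are built from explicit edit
scripts (insertions, deletions, substitutions) applied to a target
sequence, or drawn randomly from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import GAP, PairAlignment
from .errors import ModelPrepError
from .geometry import angle, dihedral, place_atom
from .residues import (AA1, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA,
                       ANGLE_N_CA_C, BOND_CA_C, BOND_C_N, BOND_C_O,
                       BOND_N_CA, IDEAL_ALA, ONE_TO_THREE, SIDE_CHAIN_ZMAT)
from .structure import (Atom, Chain, Residue, SecondaryStructure, Structure,
                        classify_chains)

CONFORMATIONS = {
    "ideal-helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}

# CB placement parameters measured on the ideal alanine reference, so the
# fixture chirality matches the Cβ-reconstruction reference exactly.
_CB_BOND = float(np.linalg.norm(IDEAL_ALA["CB"] - IDEAL_ALA["CA"]))
_CB_ANGLE = angle(IDEAL_ALA["N"], IDEAL_ALA["CA"], IDEAL_ALA["CB"])
_CB_DIHEDRAL = dihedral(IDEAL_ALA["C"], IDEAL_ALA["N"], IDEAL_ALA["CA"],
                        IDEAL_ALA["CB"])


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy chain: sequence, conformation, optional jitter."""

    sequence: str
    conformation: str = "ideal-helix"
    chain_id: str = "A"
    jitter: float = 0.0  # Å, Gaussian, applied to every coordinate
    seed: int = 0
    default_b: float = 20.0


def _backbone(n_res: int, phi: float, psi: float):
    """Ideal backbone coordinates: list of (N, CA, C, O) per residue."""
    coords = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    theta = np.deg2rad(180.0 - ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    for i in range(n_res):
        n_next = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        coords.append((n, ca, c, o))
        if i + 1 < n_res:
            ca_next = place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, 180.0)
            c_next = place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
    return coords


def make_structure(spec: ToySpec) -> Structure:
    """Build a toy chain with full backbone and idealized side chains."""
    if not spec.sequence:
        raise ModelPrepError("toy sequence must be non-empty")
    for ch in spec.sequence:
        if ch not in AA1:
            raise ModelPrepError(f"unknown residue letter {ch!r}")
    if spec.conformation not in CONFORMATIONS:
        raise ModelPrepError(
            f"unknown conformation {spec.conformation!r}; "
            f"available: {', '.join(CONFORMATIONS)}")
    phi, psi = CONFORMATIONS[spec.conformation]
    backbone = _backbone(len(spec.sequence), phi, psi)
    chain = Chain(chain_id=spec.chain_id)
    for i, letter in enumerate(spec.sequence):
        res_name = ONE_TO_THREE[letter]
        n, ca, c, o = backbone[i]
        res = Residue(name=res_name, seqnum=i + 1)
        pos = {"N": n, "CA": ca, "C": c, "O": o}
        for name in ("N", "CA", "C", "O"):
            res.atoms.append(Atom(name=name, element=name[0], pos=pos[name],
                                  b=spec.default_b))
        if res_name != "GLY":
            pos["CB"] = place_atom(pos["C"], pos["N"], pos["CA"],
                                   _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL)
            res.atoms.append(Atom(name="CB", element="C", pos=pos["CB"],
                                  b=spec.default_b))
        for entry in SIDE_CHAIN_ZMAT[res_name]:
            name, ra, rb, rc, bond, ang, dih = entry
            pos[name] = place_atom(pos[ra], pos[rb], pos[rc], bond, ang, dih)
            res.atoms.append(Atom(name=name, element=name[0], pos=pos[name],
                                  b=spec.default_b))
        chain.residues.append(res)
    st = Structure(chains=[chain], name="toy")
    if spec.conformation == "ideal-helix":
        st.ss_ranges.append(SecondaryStructure(
            "helix", spec.chain_id, (1, ""), (len(spec.sequence), "")))
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for atom in st.atoms():
            atom.pos = atom.pos + rng.normal(0.0, spec.jitter, 3)
    return classify_chains(st)


# --- Alignment construction ----------------------------------------------

def make_alignment(target: str, edits: list[tuple] = ()) -> PairAlignment:
    """Derive a model row from a target sequence by an edit script.

    Edits are applied to 0-based target positions, in order:
      ("substitute", pos, seq)  replace len(seq) target letters with seq
      ("delete", pos, length)   model lacks these target residues
      ("insert", pos, seq)      model has extra residues before position pos
    The resulting alignment keeps the full target row; deletions put gaps in
    the model row, insertions put gaps in the target row.
    """
    if not target:
        raise ModelPrepError("empty target sequence")
    cols = [[t, t] for t in target]  # [target char, model char]
    inserts: dict[int, str] = {}
    for op in edits:
        kind = op[0]
        if kind == "substitute":
            _, pos, seq = op
            if pos + len(seq) > len(target):
                raise ModelPrepError("substitution runs past the target end")
            for k, ch in enumerate(seq):
                cols[pos + k][1] = ch
        elif kind == "delete":
            _, pos, length = op
            if pos + length > len(target):
                raise ModelPrepError("deletion runs past the target end")
            for k in range(length):
                cols[pos + k][1] = GAP
        elif kind == "insert":
            _, pos, seq = op
            inserts[pos] = inserts.get(pos, "") + seq
        else:
            raise ModelPrepError(f"unknown edit {kind!r}")
    t_row, m_row = [], []
    for i in range(len(target) + 1):
        if i in inserts:
            t_row.append(GAP * len(inserts[i]))
            m_row.append(inserts[i])
        if i < len(target):
            t_row.append(cols[i][0])
            m_row.append(cols[i][1])
    return PairAlignment("".join(t_row), "".join(m_row))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA1)) for _ in range(length))


def random_alignment(rng: np.random.Generator, length: int,
                     gap_fraction: float = 0.2,
                     substitution_rate: float = 0.3) -> PairAlignment:
    """Random pairwise alignment with mixed matches, mismatches and indels.

    `gap_fraction` is the approximate fraction of columns carrying a gap
    (split between insertions and deletions); substituted columns carry a
    random different residue.
    """
    target = random_sequence(rng, length)
    edits: list[tuple] = []
    n_gap = int(round(gap_fraction * length))
    n_ins = n_gap // 2
    n_del = n_gap - n_ins
    deleted: set[int] = set()
    if n_del:
        pos = int(rng.integers(0, max(1, length - n_del)))
        edits.append(("delete", pos, n_del))
        deleted = set(range(pos, pos + n_del))
    for i in range(length):
        if i not in deleted and rng.random() < substitution_rate:
            choices = [a for a in AA1 if a != target[i]]
            edits.append(("substitute", i, rng.choice(choices)))
    if n_ins:
        pos = int(rng.integers(0, length + 1))
        edits.append(("insert", pos, random_sequence(rng, n_ins)))
    return make_alignment(target, edits)
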