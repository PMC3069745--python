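"""Side-chain editing: atom correspondence, pruning levels, Cβ completion.

Equivalent side-chain atoms of two residue types are found as a maximal
common connected subgraph of their covalent topology graphs, anchored at
the CA-CB bond.  Pruning keeps the full mapped side chain above the
full-length threshold, truncates to a single γ-position atom between the
thresholds and truncates to Cβ below the (optional) Cγ threshold.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .alignments import PairAlignment
from .errors import ModelPrepError
from .geometry import kabsch_transform
from .residues import (GAMMA_ATOMS, GAMMA_PREFERENCE, IDEAL_ALA,
                       ONE_TO_THREE, SIDE_CHAIN_BONDS, STANDARD_AA,
                       element_of, side_chain_atoms)
from .scoring import SimilarityProfile
from .structure import Chain, Residue

BACKBONE_SET = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomCorrespondence:
    """Mapping between side-chain atoms of a model and a target residue type."""

    model_type: str
    target_type: str
    pairs: dict[str, str]  # model atom -> target atom (includes CA, CB)
    unmatched_model_atoms: tuple[str, ...]


@dataclass(frozen=True)
class PruneRule:
    """Similarity thresholds for the two truncation levels."""

    full_threshold: float
    cgamma_threshold: float | None = None

    def __post_init__(self):
        if (self.cgamma_threshold is not None
                and self.cgamma_threshold >= self.full_threshold):
            raise ModelPrepError(
                "cgamma_threshold must be below full_threshold")

    def level(self, score: float) -> str:
        if score >= self.full_threshold:
            return "full"
        if self.cgamma_threshold is not None and score < self.cgamma_threshold:
            return "beta"
        return "gamma"


def _adjacency(res_name: str) -> dict[str, frozenset[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in SIDE_CHAIN_BONDS[res_name]:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    adj.setdefault("CA", set())
    return {k: frozenset(v) for k, v in adj.items()}


def _mapping_stats(pairs: dict[str, str]) -> tuple[int, int, int]:
    size = len(pairs)
    elem = sum(element_of(m) == element_of(t) for m, t in pairs.items())
    name = sum(m == t for m, t in pairs.items())
    return size, elem, name


def _canonical(pairs: dict[str, str]):
    # Direction-symmetric representation, used as the deterministic tie-break.
    return sorted(tuple(sorted((m, t))) for m, t in pairs.items())


@functools.lru_cache(maxsize=None)
def map_atoms(model_type: str, target_type: str) -> AtomCorrespondence:
    """Best common-subgraph atom mapping between two residue types.

    The search grows a connected, adjacency-preserving injective mapping out
    from the anchored CA-CB pair, maximizing first the number of mapped
    atoms, then element agreement, then name agreement; remaining ties are
    resolved by a direction-symmetric canonical ordering, so the mapping of
    (A, B) inverts that of (B, A).  Unmatched model atoms are slated for
    deletion.
    """
    for t in (model_type, target_type):
        if t not in STANDARD_AA:
            raise ModelPrepError(f"unknown residue type {t!r}")
    m_adj = _adjacency(model_type)
    t_adj = _adjacency(target_type)
    m_atoms = side_chain_atoms(model_type)
    anchor = {"CA": "CA"}
    if "CB" in m_adj and "CB" in t_adj:
        anchor["CB"] = "CB"
    best: dict = {"pairs": dict(anchor)}

    def better(cand: dict[str, str]) -> bool:
        cs, ce, cn = _mapping_stats(cand)
        bs, be, bn = _mapping_stats(best["pairs"])
        if (cs, ce, cn) != (bs, be, bn):
            return (cs, ce, cn) > (bs, be, bn)
        return _canonical(cand) < _canonical(best["pairs"])

    def extend(mapping: dict[str, str], skipped: frozenset[str]):
        # deterministic frontier: smallest unvisited model atom adjacent to
        # the mapped set
        frontier = sorted(
            u for u in m_adj
            if u not in mapping and u not in skipped
            and any(v in mapping for v in m_adj[u]))
        if not frontier:
            if better(mapping):
                best["pairs"] = dict(mapping)
            return
        u = frontier[0]
        used = set(mapping.values())
        candidates = sorted({
            t for v in m_adj[u] if v in mapping
            for t in t_adj.get(mapping[v], frozenset()) if t not in used})
        for t in candidates:
            ok = all((v2 in m_adj[u]) == (mapping[v2] in t_adj.get(t, frozenset()))
                     for v2 in mapping)
            if ok:
                mapping[u] = t
                extend(mapping, skipped)
                del mapping[u]
        extend(mapping, skipped | {u})

    extend(dict(anchor), frozenset())
    pairs = best["pairs"]
    unmatched = tuple(a for a in m_atoms if a not in pairs)
    return AtomCorrespondence(model_type=model_type, target_type=target_type,
                              pairs=dict(pairs), unmatched_model_atoms=unmatched)


def _choose_gamma(present: list[str], mapped: set[str] | None) -> str | None:
    pool = [a for a in present if a in GAMMA_ATOMS]
    if mapped is not None:
        mapped_pool = [a for a in pool if a in mapped]
        if mapped_pool:
            pool = mapped_pool
    for name in GAMMA_PREFERENCE:
        if name in pool:
            return name
    return pool[0] if pool else None


def prune_residue(res: Residue, score: float, rule: PruneRule,
                  target_letter: str | None, rename: bool = True) -> bool:
    """Apply mapping and truncation to one residue; True if atoms changed.

    `target_letter` is the one-letter target residue at this alignment
    column (None when aligned with a gap or an unknown residue).  Glycine
    and non-standard residues are never modified.
    """
    if res.name == "GLY" or res.name not in STANDARD_AA:
        return False
    target_type = ONE_TO_THREE.get(target_letter) if target_letter else None
    corr = None
    if target_type is not None and target_type != res.name:
        corr = map_atoms(res.name, target_type)
    level = rule.level(score)
    side_present = [a.name for a in res.atoms if a.name not in BACKBONE_SET]
    keep: set[str]
    if corr is None:
        mapped_side = None
    else:
        mapped_side = {m for m in corr.pairs if m not in ("CA",)}
    if level == "full":
        keep = set(side_present) if mapped_side is None else mapped_side
    elif level == "gamma":
        gamma = _choose_gamma(side_present, mapped_side)
        keep = {"CB"} | ({gamma} if gamma else set())
        if mapped_side is not None:
            keep &= mapped_side
    else:  # beta
        keep = {"CB"}
        if mapped_side is not None:
            keep &= mapped_side
    removed = [a for a in res.atoms
               if a.name not in BACKBONE_SET and a.name not in keep]
    res.atoms = [a for a in res.atoms
                 if a.name in BACKBONE_SET or a.name in keep]
    changed = bool(removed)
    if rename and corr is not None and level == "full":
        for atom in res.atoms:
            if atom.name in corr.pairs:
                new_name = corr.pairs[atom.name]
                if new_name != atom.name:
                    atom.name = new_name
                    atom.element = element_of(new_name)
                    changed = True
        res.name = target_type
    return changed


def prune_side_chains(chain: Chain, alignment: PairAlignment,
                      profile: SimilarityProfile, rule: PruneRule,
                      model_indices: list[int] | None = None,
                      rename: bool = True) -> int:
    """Prune every residue of a paired chain; returns the residues changed.

    `model_indices` gives, per chain residue, its index in the alignment's
    model sequence (defaults to 0..n-1 for an unedited chain).
    """
    if profile.positions != alignment.positions:
        raise ModelPrepError("profile length does not match alignment")
    if model_indices is None:
        model_indices = list(range(len(chain.residues)))
    if len(model_indices) != len(chain.residues):
        raise ModelPrepError("model indices do not match chain length")
    cols = alignment.model_columns()
    changed = 0
    for res, j in zip(chain.residues, model_indices):
        col = cols[j]
        score = float(profile.smoothed_scores[col])
        t = alignment.target_row[col]
        target_letter = t if t != "-" and t in ONE_TO_THREE else None
        if prune_residue(res, score, rule, target_letter, rename=rename):
            changed += 1
    return changed


_IDEAL_BACKBONE = np.array([IDEAL_ALA["N"], IDEAL_ALA["CA"], IDEAL_ALA["C"]])


def complete_cbeta(res: Residue) -> bool:
    """Add a missing Cβ by superimposing an ideal alanine on N, CA, C.

    The new atom inherits the CA B factor.  Glycine is left alone; if any
    backbone atom is missing the residue is returned unchanged with a
    warning.  Returns True when an atom was added.
    """
    if res.name == "GLY" or res.atom("CB") is not None:
        return False
    refs = [res.atom(n) for n in ("N", "CA", "C")]
    if any(a is None for a in refs):
        import warnings
        warnings.warn(f"residue {res.name} {res.seqnum}{res.icode}: "
                      "incomplete backbone, cannot place CB")
        return False
    fixed = np.array([a.pos for a in refs])
    rot, trans = kabsch_transform(_IDEAL_BACKBONE, fixed)
    cb_pos = rot @ IDEAL_ALA["CB"] + trans
    ca = res.atom("CA")
    from .structure import Atom
    res.atoms.append(Atom(name="CB", element="C", pos=cb_pos,
                          b=ca.b, occ=ca.occ))
    return True
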