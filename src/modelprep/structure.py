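"""Coordinate-file handling: read/write PDB, chain typing, alignment pairing.

The in-memory model is a plain chains -> residues -> atoms hierarchy.
Chains are typed by residue content rather than by ATOM/HETATM record, so a
chain containing selenomethionine or phosphoresidues still counts as
protein, which keeps modified positions in the search model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .alignments import PairAlignment, project_pair
from .errors import ModelPrepError
from .residues import (BACKBONE_ATOMS, MODIFIED_PARENT, STANDARD_AA,
                       THREE_TO_ONE)

PROTEIN = "protein"
HETERO = "hetero"


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) in Å
    b: float = 0.0
    occ: float = 1.0


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""  # '' or a single letter
    atoms: list[Atom] = field(default_factory=list)

    @property
    def res_id(self) -> tuple[int, str]:
        return (self.seqnum, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def is_amino(self) -> bool:
        return self.name in STANDARD_AA or self.name in MODIFIED_PARENT

    def one_letter(self) -> str:
        name = MODIFIED_PARENT.get(self.name, self.name)
        return THREE_TO_ONE.get(name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    chain_class: str | None = None

    def sequence(self) -> str:
        """One-letter sequence (modified residues mapped to parents)."""
        return "".join(r.one_letter() for r in self.residues)

    def atoms(self):
        for r in self.residues:
            yield from r.atoms


@dataclass
class SecondaryStructure:
    """One HELIX or SHEET range from the coordinate file header."""

    kind: str  # "helix" | "sheet"
    chain_id: str
    start: tuple[int, str]
    end: tuple[int, str]


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    ss_ranges: list[SecondaryStructure] = field(default_factory=list)
    name: str = ""

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.chain_class == PROTEIN]

    def atoms(self):
        for ch in self.chains:
            yield from ch.atoms()


@dataclass
class ChainAlignmentMap:
    """Pairing of protein chains with their alignments."""

    pairs: dict[str, PairAlignment] = field(default_factory=dict)
    unpaired: list[str] = field(default_factory=list)


def _icode_str(icode: str) -> str:
    return "" if icode in (" ", "\x00", "") else icode


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file (first model only; altlocs resolved by occupancy)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ModelPrepError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelPrepError(f"{path} contains no coordinates")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; using the first")
    out = Structure(name=st.name)
    model = st[0]
    for gch in model:
        chain = Chain(chain_id=gch.name)
        for gres in gch:
            res = Residue(name=gres.name.strip(),
                          seqnum=gres.seqid.num,
                          icode=_icode_str(gres.seqid.icode))
            picked: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = picked.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    picked[ga.name] = ga
            for name, ga in picked.items():  # dict keeps file order of names
                res.atoms.append(Atom(name=name,
                                      element=ga.element.name.upper(),
                                      pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                      b=ga.b_iso, occ=ga.occ))
            chain.residues.append(res)
        out.chains.append(chain)
    for h in st.helices:
        out.ss_ranges.append(SecondaryStructure(
            "helix", h.start.chain_name,
            (h.start.res_id.seqid.num, _icode_str(h.start.res_id.seqid.icode)),
            (h.end.res_id.seqid.num, _icode_str(h.end.res_id.seqid.icode))))
    for sheet in st.sheets:
        for strand in sheet.strands:
            out.ss_ranges.append(SecondaryStructure(
                "sheet", strand.start.chain_name,
                (strand.start.res_id.seqid.num,
                 _icode_str(strand.start.res_id.seqid.icode)),
                (strand.end.res_id.seqid.num,
                 _icode_str(strand.end.res_id.seqid.icode))))
    return classify_chains(out)


def classify_chains(structure: Structure) -> Structure:
    """Type each chain as protein or hetero by its residue content.

    A chain is protein when at least half of its residues are standard amino
    acids or known modified amino acids; everything else (waters, ligands,
    nucleic acids) is hetero.
    """
    if not structure.chains:
        raise ModelPrepError("structure has no chains")
    for chain in structure.chains:
        if not chain.residues:
            chain.chain_class = HETERO
            continue
        amino = sum(r.is_amino() for r in chain.residues)
        chain.chain_class = (PROTEIN if amino / len(chain.residues) >= 0.5
                             else HETERO)
    return structure


def filter_hetero(structure: Structure, keep: list[str]) -> Structure:
    """Drop hetero residues except specifically named compounds (e.g. HEM)."""
    keep_set = {k.strip().upper() for k in keep}
    kept_chains = []
    for chain in structure.chains:
        if chain.chain_class == PROTEIN:
            kept_chains.append(chain)
            continue
        chain.residues = [r for r in chain.residues
                          if r.name.upper() in keep_set]
        if chain.residues:
            kept_chains.append(chain)
    structure.chains = kept_chains
    return structure


def pair_chains(structure: Structure,
                alignments: list[PairAlignment | list[tuple[str, str]]],
                target_name: str | None = None) -> ChainAlignmentMap:
    """Match each protein chain to the alignment whose model row equals it.

    Entries in `alignments` may be ready pairwise alignments, or raw
    (name, gapped row) row lists from a multiple alignment; row lists are
    projected against each chain's sequence.  Identical chains may share one
    alignment; a chain matching several different alignments is ambiguous.
    """
    result = ChainAlignmentMap()
    for chain in structure.protein_chains():
        seq = chain.sequence()
        matches: list[PairAlignment] = []
        for aln in alignments:
            if isinstance(aln, PairAlignment):
                if aln.model_sequence == seq:
                    matches.append(aln)
            else:
                try:
                    matches.append(project_pair(aln, target_name=target_name,
                                                model_sequence=seq))
                except ModelPrepError:
                    continue
        if not matches:
            result.unpaired.append(chain.chain_id)
        elif len({(m.target_row, m.model_row) for m in matches}) > 1:
            raise ModelPrepError(
                f"chain {chain.chain_id} matches multiple alignments: "
                + "; ".join(m.model_row for m in matches))
        else:
            result.pairs[chain.chain_id] = matches[0]
    return result


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a PDB file (HELIX records for annotated helices, B to 2 dp)."""
    st = gemmi.Structure()
    st.name = structure.name or "model"
    st.add_model(gemmi.Model("1"))
    for chain in structure.chains:
        seen: set[tuple[int, str]] = set()
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            if res.res_id in seen:
                raise ModelPrepError(
                    f"duplicate residue id {res.seqnum}{res.icode} "
                    f"in chain {chain.chain_id}")
            seen.add(res.res_id)
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            amino = res.is_amino() or res.name == "GAP"
            gres.het_flag = "A" if (chain.chain_class == PROTEIN and amino) else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.b_iso = round(float(atom.b), 2)
                ga.occ = atom.occ
                gres.add_atom(ga)
            gch.add_residue(gres)
        st[0].add_chain(gch)
    for i, ss in enumerate(s for s in structure.ss_ranges if s.kind == "helix"):
        h = gemmi.Helix()
        start = gemmi.AtomAddress()
        start.chain_name = ss.chain_id
        rid = gemmi.ResidueId()
        rid.seqid = gemmi.SeqId(ss.start[0], ss.start[1] or " ")
        start.res_id = rid
        end = gemmi.AtomAddress()
        end.chain_name = ss.chain_id
        rid2 = gemmi.ResidueId()
        rid2.seqid = gemmi.SeqId(ss.end[0], ss.end[1] or " ")
        end.res_id = rid2
        h.start = start
        h.end = end
        h.pdb_helix_class = 1
        st.helices.append(h)
    st.setup_entities()
    st.write_pdb(str(path))
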