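"""Editing protocols: the 12 benchmark presets and the pipeline runner.

A protocol bundles the main-chain deletion settings (matrix, window,
threshold or "variable"), the side-chain pruning settings, and the
B-factor model.  Preset 1 reproduces the classic reference recipe: delete
residues aligned with target gaps, prune non-identical side chains to Cγ,
keep original B factors.  Presets 2-12 progressively add smoothing,
count-matched variable thresholds, BLOSUM62 pruning and similarity/ASA
B-factor models.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import asa as asa_mod
from .alignments import PairAlignment
from .bfactor import BfactorModel, assign_bfactors
from .errors import ModelPrepError
from .mainchain import (VARIABLE, apply_deletion, plan_deletion, polish_trace,
                        renumber_to_target, ss_mask_for_chain,
                        variable_threshold)
from .scoring import load_matrix, similarity_profile
from .sidechain import PruneRule, complete_cbeta, prune_side_chains
from .structure import (ChainAlignmentMap, Structure, filter_hetero,
                        pair_chains)


@dataclass(frozen=True)
class MainchainConfig:
    matrix: str = "identity"
    window: int = 0
    threshold: float | str | None = 0.0  # number, "variable", or None (off)


@dataclass(frozen=True)
class SidechainConfig:
    matrix: str = "identity"
    window: int = 0
    full_threshold: float | None = 1.0  # None switches pruning off
    cgamma_threshold: float | None = None
    rename: bool = True
    complete_cbeta: bool = True


@dataclass(frozen=True)
class PolishConfig:
    min_fragment: int = 1   # 1 = keep all fragments (off)
    max_reinstate: int = 0  # 0 = no reinstatement (off)


@dataclass(frozen=True)
class ProtocolConfig:
    """Complete parameter set of one editing protocol."""

    mainchain: MainchainConfig = MainchainConfig()
    sidechain: SidechainConfig = SidechainConfig()
    bfactor: BfactorModel = BfactorModel()
    polish: PolishConfig = PolishConfig()
    hetero_keep: tuple[str, ...] = ()
    renumber: bool = True
    asa_probe: float = asa_mod.DEFAULT_PROBE
    asa_points: int = asa_mod.DEFAULT_POINTS

    def __post_init__(self):
        for w in (self.mainchain.window, self.sidechain.window):
            if w < 0:
                raise ModelPrepError("averaging window must be non-negative")


_SIM_B = dict(mode="similarity", similarity_factor=80.0)
_ASA_B = dict(mode="asa", asa_factor=12.0)
_COMB_B = dict(mode="combined", similarity_factor=60.0, asa_factor=8.0)

# Benchmark presets.  Main-chain deletion always uses the identity matrix;
# the similarity term of B-factor models uses BLOSUM62 with window 5.
_PRESETS: dict[int, dict] = {
    1: dict(mc=("identity", 0, 0.0), sc=("identity", 0, 1.0), b=None),
    2: dict(mc=("identity", 3, 0.2), sc=("identity", 0, 1.0), b=None),
    3: dict(mc=("identity", 5, VARIABLE), sc=("identity", 0, 1.0), b=None),
    4: dict(mc=("identity", 0, 0.0), sc=("BLOSUM62", 1, 0.2), b=None),
    5: dict(mc=("identity", 5, VARIABLE), sc=("BLOSUM62", 1, 0.2), b=None),
    6: dict(mc=("identity", 0, 0.0), sc=("identity", 0, 1.0), b=_SIM_B),
    7: dict(mc=("identity", 5, VARIABLE), sc=("identity", 0, 1.0), b=_SIM_B),
    8: dict(mc=("identity", 0, 0.0), sc=("identity", 0, 1.0), b=_ASA_B),
    9: dict(mc=("identity", 5, VARIABLE), sc=("identity", 0, 1.0), b=_ASA_B),
    10: dict(mc=("identity", 0, 0.0), sc=("identity", 0, 1.0), b=_COMB_B),
    11: dict(mc=("identity", 5, VARIABLE), sc=("identity", 0, 1.0), b=_COMB_B),
    12: dict(mc=("identity", 5, VARIABLE), sc=("BLOSUM62", 1, 0.2), b=_COMB_B),
}

# The matrix/window of the similarity term in B-factor presets 6-12.
B_SIM_MATRIX = "BLOSUM62"
B_SIM_WINDOW = 5


def preset(protocol_id: int) -> ProtocolConfig:
    """The parameter set of benchmark protocol 1-12."""
    if protocol_id not in _PRESETS:
        raise ModelPrepError(f"protocol id {protocol_id} outside 1..12")
    row = _PRESETS[protocol_id]
    mc_matrix, mc_window, mc_threshold = row["mc"]
    sc_matrix, sc_window, sc_threshold = row["sc"]
    b = BfactorModel() if row["b"] is None else BfactorModel(**row["b"])
    return ProtocolConfig(
        mainchain=MainchainConfig(mc_matrix, mc_window, mc_threshold),
        sidechain=SidechainConfig(sc_matrix, sc_window, sc_threshold),
        bfactor=b)


@dataclass
class EditReport:
    """Summary of the edits made to one structure."""

    chains: dict[str, dict] = field(default_factory=dict)
    b_stats: dict[str, float] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.events.append(message)


def run_protocol(structure: Structure,
                 alignments: list[PairAlignment | list[tuple[str, str]]],
                 config: ProtocolConfig,
                 target_name: str | None = None,
                 in_place: bool = False) -> tuple[Structure, EditReport]:
    """Run the full editing pipeline on a classified structure.

    Order: hetero filtering, chain/alignment pairing, ASA on the unedited
    structure (when an ASA-based B model is requested), similarity profiles,
    main-chain deletion and polish, side-chain pruning and Cβ completion,
    renumbering to target numbering, B-factor assignment.
    """
    if not in_place:
        structure = copy.deepcopy(structure)
    report = EditReport()
    filter_hetero(structure, list(config.hetero_keep))
    report.log(f"hetero filter: kept compounds {list(config.hetero_keep)}")
    pairing: ChainAlignmentMap = pair_chains(structure, alignments,
                                             target_name=target_name)
    for cid in pairing.unpaired:
        report.log(f"chain {cid}: no matching alignment")

    asa_result = None
    if config.bfactor.mode in ("asa", "combined"):
        asa_result = asa_mod.compute_asa(structure, probe=config.asa_probe,
                                         n=config.asa_points)
        report.log(f"ASA computed on original structure "
                   f"({asa_result.mesh_points} mesh points)")

    mc_matrix = load_matrix(config.mainchain.matrix)
    sc_matrix = load_matrix(config.sidechain.matrix)
    b_matrix = load_matrix(B_SIM_MATRIX)

    b_profiles: dict = {}
    kept_indices: dict[str, list[int]] = {}
    for chain in structure.protein_chains():
        aln = pairing.pairs.get(chain.chain_id)
        if aln is None:
            if (config.mainchain.threshold is not None
                    or config.sidechain.full_threshold is not None
                    or config.bfactor.mode in ("similarity", "combined")):
                raise ModelPrepError(
                    f"chain {chain.chain_id} is unpaired but the protocol "
                    "requires an alignment")
            continue
        n_in = len(chain.residues)
        indices = list(range(n_in))

        if config.mainchain.threshold is not None:
            profile = similarity_profile(aln, mc_matrix,
                                         config.mainchain.window)
            if config.mainchain.threshold == VARIABLE:
                t = variable_threshold(profile, aln)
                report.log(f"chain {chain.chain_id}: variable threshold {t:.4f}")
            else:
                t = float(config.mainchain.threshold)
            plan = plan_deletion(profile, aln, t)
            mask = ss_mask_for_chain(chain, structure.ss_ranges)
            plan = polish_trace(plan, ss_mask=mask,
                                min_fragment=config.polish.min_fragment,
                                max_reinstate=config.polish.max_reinstate)
            indices = apply_deletion(chain, plan)
            report.log(f"chain {chain.chain_id}: kept {len(indices)}/{n_in} "
                       f"residues (threshold {t:.4f})")

        if config.sidechain.full_threshold is not None:
            sc_profile = similarity_profile(aln, sc_matrix,
                                            config.sidechain.window)
            rule = PruneRule(full_threshold=config.sidechain.full_threshold,
                             cgamma_threshold=config.sidechain.cgamma_threshold)
            n_pruned = prune_side_chains(chain, aln, sc_profile, rule,
                                         model_indices=indices,
                                         rename=config.sidechain.rename)
            report.log(f"chain {chain.chain_id}: pruned {n_pruned} side chains")
            if config.sidechain.complete_cbeta:
                added = sum(complete_cbeta(res) for res in chain.residues)
                if added:
                    report.log(f"chain {chain.chain_id}: added {added} CB atoms")

        if config.renumber:
            renumber_to_target(chain, aln, kept_indices=indices)
            n_gap = sum(r.name == "GAP" for r in chain.residues)
            if n_gap:
                report.log(f"chain {chain.chain_id}: {n_gap} GAP residues")

        kept_indices[chain.chain_id] = indices
        if config.bfactor.mode in ("similarity", "combined"):
            b_profiles[chain.chain_id] = similarity_profile(
                aln, b_matrix, B_SIM_WINDOW)
        report.chains[chain.chain_id] = {
            "residues_in": n_in,
            "residues_out": len(chain.residues),
            "gap_residues": sum(r.name == "GAP" for r in chain.residues),
        }

    assign_bfactors(structure, config.bfactor, profiles=b_profiles,
                    alignments=pairing.pairs, asa=asa_result,
                    model_indices=kept_indices)
    b_all = np.array([a.b for a in structure.atoms()])
    if b_all.size:
        report.b_stats = {"min": float(b_all.min()),
                          "max": float(b_all.max()),
                          "mean": float(b_all.mean())}
    return structure, report
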