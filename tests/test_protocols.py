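"""Protocol presets and the end-to-end editing pipeline."""

import numpy as np
import pytest

from modelprep import (ModelPrepError, PairAlignment, ToySpec, make_alignment,
                       make_structure, preset, run_protocol, write_structure)
from modelprep.mainchain import VARIABLE
from modelprep.protocols import (MainchainConfig, ProtocolConfig,
                                 SidechainConfig)
from modelprep.residues import ONE_TO_THREE, STANDARD_AA, side_chain_atoms
from modelprep.sidechain import map_atoms
from modelprep.structure import Chain, Residue, Atom, classify_chains


class TestPresets:
    def test_preset_1_reference_row(self):
        cfg = preset(1)
        assert cfg.mainchain == MainchainConfig("identity", 0, 0.0)
        assert cfg.sidechain.matrix == "identity"
        assert cfg.sidechain.window == 0
        assert cfg.sidechain.full_threshold == 1.0
        assert cfg.bfactor.mode == "original"

    def test_preset_3_variable_threshold(self):
        cfg = preset(3)
        assert cfg.mainchain == MainchainConfig("identity", 5, VARIABLE)
        assert cfg.bfactor.mode == "original"

    def test_preset_8_asa_b(self):
        cfg = preset(8)
        assert cfg.mainchain.window == 0
        assert cfg.bfactor.mode == "asa"
        assert cfg.bfactor.asa_factor == 12.0

    def test_preset_11_combined(self):
        cfg = preset(11)
        assert cfg.mainchain.threshold == VARIABLE
        assert cfg.bfactor.mode == "combined"
        assert cfg.bfactor.similarity_factor == 60.0
        assert cfg.bfactor.asa_factor == 8.0

    def test_preset_12_adds_sidechain_pruning(self):
        cfg = preset(12)
        assert cfg.sidechain == SidechainConfig("BLOSUM62", 1, 0.2)
        assert cfg.bfactor.mode == "combined"

    def test_presets_6_7_similarity_b(self):
        for pid in (6, 7):
            cfg = preset(pid)
            assert cfg.bfactor.mode == "similarity"
            assert cfg.bfactor.similarity_factor == 80.0

    @pytest.mark.parametrize("bad", [0, 13, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ModelPrepError):
            preset(bad)


def reference_edit(structure, alignment):
    """Independent column-scan oracle for the reference recipe (preset 1).

    Keeps exactly the model residues aligned with target residues; identical
    pairs keep their side chain, all others keep the mapped-and-truncated
    stub up to the gamma position; B factors untouched.
    """
    out = []
    j = 0
    chain = structure.chains[0]
    for t, m in zip(alignment.target_row, alignment.model_row):
        if m == "-":
            continue
        res = chain.residues[j]
        j += 1
        if t == "-":
            continue
        names = {a.name for a in res.atoms}
        if t == res.one_letter() or res.name == "GLY":
            kept = names
            name = res.name
        else:
            corr = map_atoms(res.name, ONE_TO_THREE[t])
            mapped = set(corr.pairs) - {"CA"}
            gammas = [g for g in ("CG", "CG1", "OG", "OG1", "SG", "CG2")
                      if g in names]
            mapped_g = [g for g in gammas if g in mapped]
            # the gamma survivor must itself be mapped; preference order with
            # CG2 as the last resort
            gamma = mapped_g[0] if mapped_g else None
            kept = {n for n in names if n in ("N", "CA", "C", "O", "OXT")}
            kept |= {"CB"} & mapped & names
            if gamma:
                kept.add(gamma)
            name = res.name
        out.append((name, tuple(sorted(kept))))
    return out


class TestRunProtocol:
    def test_perfect_self_alignment_preset1_is_identity(self, small_helix):
        seq = small_helix.chains[0].sequence()
        aln = PairAlignment(seq, seq)
        edited, report = run_protocol(small_helix, [aln], preset(1))
        orig = [(r.name, [a.name for a in r.atoms], [tuple(a.pos) for a in r.atoms])
                for r in small_helix.chains[0].residues]
        new = [(r.name, [a.name for a in r.atoms], [tuple(a.pos) for a in r.atoms])
               for r in edited.chains[0].residues]
        assert orig == new
        bs_before = [a.b for a in small_helix.atoms()]
        bs_after = [a.b for a in edited.atoms()]
        assert bs_before == bs_after

    def test_insertion_alignment_preset1_deletes_gap_survivors(
            self, helix_structure, insertion_alignment):
        edited, report = run_protocol(helix_structure, [insertion_alignment],
                                      preset(1))
        assert len(edited.chains[0].residues) == 10
        assert all(r.name != "GAP" for r in edited.chains[0].residues)
        assert report.chains["A"]["residues_out"] == 10

    def test_variable_threshold_count_matching(self):
        rng = np.random.default_rng(41)
        aln = None
        from modelprep import random_alignment
        aln = random_alignment(rng, 40, gap_fraction=0.25)
        st = make_structure(ToySpec(aln.model_sequence))
        edited, _ = run_protocol(st, [aln], preset(3))
        n_res = len(edited.chains[0].residues)
        assert n_res == aln.n_aligned

    def test_protocol1_equivalence_with_column_scan_oracle(self):
        from modelprep import random_alignment
        rng = np.random.default_rng(47)
        for _ in range(30):
            aln = random_alignment(rng, int(rng.integers(10, 30)))
            st = make_structure(ToySpec(aln.model_sequence))
            expected = reference_edit(st, aln)
            cfg = ProtocolConfig(
                mainchain=preset(1).mainchain,
                sidechain=SidechainConfig("identity", 0, 1.0, rename=False,
                                          complete_cbeta=False),
                bfactor=preset(1).bfactor)
            edited, _ = run_protocol(st, [aln], cfg)
            got = [(r.name, tuple(sorted(a.name for a in r.atoms)))
                   for r in edited.chains[0].residues]
            assert got == expected

    def test_byte_identical_determinism(self, tmp_path):
        aln = make_alignment("AVLKSEAVLKSE", [("delete", 3, 2),
                                              ("substitute", 7, "G")])
        st = make_structure(ToySpec(aln.model_sequence))
        paths = []
        for i in (1, 2):
            edited, _ = run_protocol(st, [aln], preset(12))
            p = tmp_path / f"out{i}.pdb"
            write_structure(edited, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_disabled_stage_equals_vacuous_threshold(self, small_helix):
        seq = small_helix.chains[0].sequence()
        aln = PairAlignment(seq, seq)
        off = ProtocolConfig(
            mainchain=MainchainConfig("identity", 0, None),
            sidechain=SidechainConfig("identity", 0, None))
        vacuous = ProtocolConfig(
            mainchain=MainchainConfig("identity", 0, -10.0),
            sidechain=SidechainConfig("identity", 0, -10.0))
        e1, _ = run_protocol(small_helix, [aln], off)
        e2, _ = run_protocol(small_helix, [aln], vacuous)
        snap = lambda st: [(r.name, [a.name for a in r.atoms])
                           for r in st.chains[0].residues]
        assert snap(e1) == snap(e2)

    def test_all_deleted_raises(self, helix_structure, insertion_alignment):
        cfg = ProtocolConfig(mainchain=MainchainConfig("identity", 0, 5.0))
        with pytest.raises(ModelPrepError, match="lower threshold"):
            run_protocol(helix_structure, [insertion_alignment], cfg)

    def test_unpaired_chain_with_similarity_stage_raises(self, small_helix):
        aln = PairAlignment("WWWW", "WWWW")  # matches nothing
        with pytest.raises(ModelPrepError, match="unpaired"):
            run_protocol(small_helix, [aln], preset(1))

    def test_unpaired_chain_allowed_for_asa_only(self, small_helix):
        cfg = ProtocolConfig(
            mainchain=MainchainConfig("identity", 0, None),
            sidechain=SidechainConfig("identity", 0, None),
            bfactor=preset(8).bfactor, renumber=False)
        edited, _ = run_protocol(small_helix, [], cfg)
        assert min(a.b for a in edited.atoms()) == pytest.approx(10.0)

    def test_hetero_removed_unless_kept(self, small_helix):
        import copy
        st = copy.deepcopy(small_helix)
        het = Chain("W", [Residue("HOH", i + 1, "",
                                  [Atom("O", "O", np.array([50.0, 0, i]))])
                          for i in range(5)]
                    + [Residue("HEM", 99, "",
                               [Atom("FE", "FE", np.array([60.0, 0, 0]))])])
        st.chains.append(het)
        classify_chains(st)
        seq = st.chains[0].sequence()
        aln = PairAlignment(seq, seq)
        cfg = preset(1)
        edited, _ = run_protocol(st, [aln], cfg)
        assert [c.chain_id for c in edited.chains] == ["A"]
        from dataclasses import replace
        cfg_keep = replace(cfg, hetero_keep=("HEM",))
        edited2, _ = run_protocol(st, [aln], cfg_keep)
        het_res = [r.name for c in edited2.chains
                   if c.chain_class == "hetero" for r in c.residues]
        assert het_res == ["HEM"]

    def test_gap_survivors_renumbered_with_insertion_codes(self):
        # long window rescues the short insertion inside a conserved stretch
        aln = make_alignment("A" * 20, [("insert", 10, "VL")])
        st = make_structure(ToySpec(aln.model_sequence))
        cfg = ProtocolConfig(
            mainchain=MainchainConfig("identity", 5, -0.5),
            sidechain=SidechainConfig("identity", 0, None))
        edited, report = run_protocol(st, [aln], cfg)
        gaps = [r for r in edited.chains[0].residues if r.name == "GAP"]
        assert [(g.seqnum, g.icode) for g in gaps] == [(10, "A"), (10, "B")]
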