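# modelprep

Search-model preparation for molecular replacement (MR). Given the
structure of a homologue and a sequence alignment to the target protein,
`modelprep` produces edited search models: it deletes main-chain segments
that the alignment says are unreliable, prunes side chains to Cβ/Cγ stubs
where the residue type changes, and re-estimates atomic B factors from
sequence similarity and solvent accessibility so that Phaser-style
likelihood targets can down-weight the parts of the model most likely to be
wrong. Twelve ready-made editing protocols are provided as presets.

## Who this is for

Crystallographers and structural bioinformaticians preparing MR search
models from distant homologues (roughly 15–45 % sequence identity), where
the unedited template is often a poor model and simple, fast edits driven by
the alignment measurably improve the chance of a solution.

## The model

**Similarity profiles.** Each alignment column *i* is scored with a
normalized substitution matrix *s*(*a*,*b*): the identity (binary) matrix
scores 1.0 for identical residues, 0.0 for mismatches and −1.0 against a
gap; PAM250/BLOSUM50/BLOSUM62 are rescaled affinely,

    s'(a,b) = (s(a,b) − E_rand) / (E_match − E_rand),

with `E_rand = Σ p_a p_b s(a,b)` and `E_match = Σ p_a s(a,a)` under uniform
background frequencies *p*, so a perfect alignment scores ≈ 1.0 and a random
one ≈ 0.0; gap columns score −1.0. The per-column scores are smoothed with a
triangular moving average of half-width *W* (weights `W+1−|k|`, truncated and
renormalized at the ends), which propagates indel information to neighbouring
residues and filters alignment noise.

**Main-chain deletion.** A model residue is kept iff its smoothed score ≥ *t*.
Residues aligned to target gaps can survive smoothing; they are renamed `GAP`
and numbered with insertion codes (12A, 12B, …). The *variable* threshold
picks *t* as the *n*-th largest score so that the model retains exactly as
many residues as there are aligned positions — the empirically optimal count.

**Side-chain pruning.** Side-chain atoms of the model type are mapped onto
the target type by a maximal common connected subgraph of the covalent
topology anchored at Cα–Cβ; atoms without a counterpart are deleted. Above
the full-length threshold the mapped side chain is kept (optionally renamed);
between the Cγ and full thresholds it is truncated to a single γ atom; below
the Cγ threshold to Cβ. Missing Cβ atoms are rebuilt by least-squares
superposition of an ideal alanine onto N, Cα, C.

**B factors.** `B = −c_sim·s_res + c_asa·a_atom`, with per-residue smoothed
similarity *s* and per-atom Shrake–Rupley accessible surface area *a*
computed on the unedited structure; the distribution is shifted by a
constant, when needed, so the minimum is exactly 10 Å².

## Worked example

```sh
# build a toy input: a 12-residue helix whose model carries a 2-residue
# insertion and one substitution relative to the target
modelprep fixtures --sequence AVLKSEAVLKSE --insert 6:GG --substitute 2:K \
    --pdb-out model.pdb --alignment-out aln.fasta
# edit it with protocol 12 (variable-threshold deletion, BLOSUM62 pruning,
# combined similarity+ASA B factors)
modelprep run --model model.pdb --alignment aln.fasta --protocol 12 \
    --output edited.pdb --log edit.json
```

which prints

```
protocol 12: wrote edited.pdb (B min 10.00, max 497.77)
```

The edited model retains the 12 aligned residues (the two inserted glycines
are deleted by the variable threshold). The model lysine opposite the
target's leucine scores above the BLOSUM62 pruning threshold, so it is
remodelled rather than truncated: its atoms are mapped onto leucine
(Cδ→Cδ1), the unmappable tail atoms Cε and Nζ are deleted and the residue
is renamed LEU. Every atom's B factor now encodes its expected error: the
floor of 10.00 Å² sits on the most conserved, most buried atom, while
497.77 Å² marks the most exposed atom of the least conserved stretch.
`edit.json` records every stage decision per chain.

The same pipeline is available as a library:

```python
from modelprep import preset, run_protocol, read_structure, read_alignment_rows
structure = read_structure("model.pdb")
rows = read_alignment_rows("aln.fasta")
edited, report = run_protocol(structure, [rows], preset(12))
```

`--protocol all` writes twelve output files (`edited_p1.pdb` …
`edited_p12.pdb`) for multi-model MR searches.

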