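# Methods

This note describes the algorithms implemented in `modelprep`, the
parameters that matter, the numerical conventions, and what the synthetic
test fixtures do and do not demonstrate.

## Similarity profiles

Alignment columns are scored with a normalized substitution matrix and
smoothed with a triangular moving average.

*Normalization.* Raw integer matrices (PAM250, BLOSUM50, BLOSUM62, taken
from Biopython's bundled tables) are rescaled affinely so that, under
background residue frequencies *p*, the mean self-match score is exactly
1.0 and the expected score of a random residue pair is exactly 0.0:
`s' = (s − E_rand)/(E_match − E_rand)`. Background frequencies are uniform
(1/20): the target scale ("about 1.0 / about 0.0") does not prescribe a
frequency model, and the uniform choice is reproducible and
matrix-independent. The gap score is fixed at −1.0 for all matrices and
applied whenever either row of a column carries a gap, for insertions and
deletions alike. The *identity* matrix is not passed through the affine
rule; it is defined directly as the binary residue/gap matrix (1.0
identical, 0.0 otherwise, −1.0 gap). Applying the affine rule to the raw
binary table would instead give slightly negative off-diagonals
(−1/19 ≈ −0.053), because the random expectation of the binary table is
1/20, not 0; the direct definition is the one used for main-chain deletion
thresholds. Unknown residues ('X' or any unrecognized letter) score 0.0
against every residue — neutral — and −1.0 against gaps.

*Smoothing.* Triangular weights `w_k = W+1−|k|` for offsets |k| ≤ W; at
sequence ends the window truncates and the weights renormalize over the
available positions (no padding — padding would invent phantom columns).
W = 0 reproduces the raw scores exactly. Gap columns inside a window
contribute their −1.0 score; they are not skipped, so proximity to an
indel genuinely depresses neighbouring scores — this is the mechanism that
lets smoothing delete residues *near* a gap and rescue isolated gap
survivors.

*Multiple alignments.* The target row is the first row unless named; the
model row is located by ungapped identity with the chain sequence; all
other rows are ignored and columns gapped in both projected rows are
dropped.

## Structure handling

Chains are typed by residue content, not by ATOM/HETATM record: a chain is
protein when at least half its residues are standard amino acids or known
modified amino acids (MSE, CSO, SEP, TPO, PTR, mapped to their parents in
the one-letter sequence). The 0.5 fraction is this package's
quantification of "mostly amino acids". Hetero chains are deleted except
for compounds named explicitly (e.g. `--keep-hetero HEM`). Alternate
locations are resolved to the highest occupancy (first wins ties); only
the first model of a multi-model file is used. Modified residues are
never side-chain pruned or atom-mapped (their atom names are not covered
by the standard topology tables); they pass through main-chain deletion
and B-factor assignment like any other residue.

## Accessible surface area

Shrake–Rupley spherical-mesh algorithm: each atom's solvent-expanded
sphere (van der Waals radius + probe) is sampled with a golden-section
spiral of *n* points; a point is accessible iff it lies strictly outside
every other atom's expanded sphere (a point exactly on a neighbouring
sphere counts as accessible, which makes degenerate contacts
deterministic). Defaults: probe 1.4 Å (water), n = 960,
radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, other 1.80 Å.
Hydrogens are included if present; no protonation is added. ASA is always
computed on the structure *before* any deletion, so the areas reflect the
original molecular context, and retained hetero atoms both receive areas
and occlude protein atoms. Isolated atoms are exact for any mesh size
(all points accessible ⇒ area = 4π(r+probe)²); overlap cases converge as
1/n and agree with the analytic spherical-cap formula to better than 2 %
at n = 10⁴. Cβ atoms rebuilt after the ASA pass have no measured area and
enter ASA-based B-factor models with area 0.

## Main-chain deletion

A model residue is kept iff its smoothed score ≥ t (inclusive). The
inclusive rule makes the identity matrix with W = 0, t = 0 reproduce the
classic reference recipe exactly: mismatches score 0.0 and are kept,
gap-aligned residues score −1.0 and are deleted.

*Variable threshold.* t is the n-th largest smoothed score over
model-residue columns, n being the number of aligned (residue/residue)
columns; the kept count then equals n exactly unless scores tie at t, in
which case all tied residues are kept (over-keeping is preferred to an
arbitrary split). With ±1/0 raw scores and small windows, ties at the
threshold do occur; the count-matching guarantee is stated for tie-free
profiles.

*Polish.* Optionally, kept fragments shorter than `min_fragment` are
deleted and deleted runs of ≤ `max_reinstate` residues are reinstated when
flanked by kept residues and lying entirely inside a HELIX/SHEET
annotation from the input file (no geometric secondary-structure
assignment is performed). Defaults are 3/3 when the polish stage is
enabled. The twelve presets leave polishing off, so preset 1 remains
exactly equivalent to the reference column-scan recipe.

*Renumbering.* Kept residues aligned to target residues take the target's
1-based sequence position; kept gap survivors are renamed GAP and numbered
with the last preceding target number plus insertion codes A, B, C…
(more than 26 consecutive survivors exhausts the codes and is an error).
Renumbering happens after pruning so insertion codes reflect the final
trace.

## Side-chain pruning

*Atom correspondence.* Residue topologies (heavy atoms, covalent bonds)
are embedded; proline keeps its ring closure through N. The mapping
between two types is the maximal common connected induced subgraph
anchored at Cα–Cβ, found by exhaustive backtracking (≤ 11 side-chain
atoms, cached per type pair). Ties are broken by preferring element
agreement, then name agreement, then a direction-symmetric canonical
ordering — the symmetry makes map(A,B) and map(B,A) inverses by
construction, which is verified exhaustively over all 400 type pairs.

*Pruning levels.* With smoothed side-chain score s:
s ≥ full threshold → keep the mapped atoms, delete unmatched ones, and
(by default) rename residue and atoms to the target type;
Cγ threshold ≤ s < full threshold (or no Cγ threshold set) → truncate to
Cβ plus exactly one γ atom; s < Cγ threshold → truncate to Cβ. The γ
survivor must itself be mapped when a correspondence exists (preference
order CG > CG1 > OG > OG1 > SG, with CG2 as last resort), so the pruned
atom set is always a subset of the full-level set and raising the full
threshold can never add atoms. The Cγ threshold is unset by default
(single-level mode, as in the presets). Renaming is applied only at the
full level, where the retained atoms are consistent with the new type;
γ/β stubs keep the model residue name. Glycine is never modified.

*Cβ completion.* Missing Cβ atoms (on non-glycine residues with complete
N/Cα/C) are rebuilt by least-squares (Kabsch) superposition of an ideal
alanine onto the residue backbone; the new atom inherits the Cα B factor.
The ideal alanine is a standard ideal-geometry reference (Cβ 1.526 Å from
Cα); rebuilt positions land within 0.05 Å of ideally constructed ones.

## B factors

`B_atom = −c_sim · s_residue + c_asa · a_atom` with the mode selecting
either or both terms. Similarity contributes per residue (one score per
alignment position, shared by all atoms of the residue); ASA contributes
per atom. Factors are quoted positive; the negative sign of the similarity
term is internal. After assignment, if the minimum over all protein atoms
falls below the floor (10 Å² by default) a single constant is added to
every atom so the minimum equals the floor exactly — a pure translation
that preserves ranks and pairwise differences, and is harmless downstream
because structure factors are normalized before use. The shift is joint
over all protein chains so inter-chain weighting survives. Hetero atoms
retained in the output keep their original B in every mode. ASA is never
rescaled after main-chain deletion (it is deliberately the pre-deletion
area).

## Protocol presets

The twelve presets cover: the reference recipe (1); fixed-threshold
smoothed deletion (2: W=3, t=0.2); variable-threshold deletion (3: W=5);
BLOSUM62 side-chain pruning at W=1, t=0.2 (4, 5); similarity-based B
factors, BLOSUM62 W=5 factor 80 (6, 7); ASA-based B factors, factor 12
(8, 9); combined B factors, factors 60 + 8 (10, 11); and the all-methods
combination (12). Main-chain deletion always uses the identity matrix.
Pipeline order: hetero filter → chain/alignment pairing → ASA (on the
unedited structure) → profiles → deletion → polish → pruning/Cβ →
renumber/rename → B factors. Protocol 2's fixed 0.2 threshold is used at
face value on the normalized smoothed-score scale.

## Synthetic fixtures and what tests demonstrate

The toy generator builds chains from ideal internal coordinates
(α-helix φ/ψ = −57°/−47° or extended −139°/135°, ω = 180°, Engh &
Huber-style bond lengths and angles, idealized side-chain rotamers with
approximate ring closure) with optional seeded Gaussian jitter; helix
fixtures carry a HELIX record. Alignments are derived from explicit edit
scripts or a seeded random generator (default study conditions for the
count-matching check: lengths 50–150, 10–30 % gap columns, ~30 %
substitutions). These fixtures exercise topology, bookkeeping and the
exact editing rules; they do not reproduce real packing, solvation or
rotamer distributions, so passing tests demonstrates algorithmic
correctness, not improvement of real MR success rates — establishing the
latter requires diffraction-data benchmarks that are out of scope here.
Problem sizes in the test suite (alignments ≤ 150 columns, meshes ≤ 10⁴
points, 200-case equivalence sweeps) were chosen to probe the asymptotic
claims at desk scale.

## Known limitations

- PDB format only (no mmCIF); nucleic-acid chains are classified hetero
  and dropped unless kept by name.
- No rotamer repacking, loop rebuilding or alignment correction; atoms
  beyond Cβ are never predicted.
- Secondary structure for trace polishing comes solely from file
  HELIX/SHEET records.
- Modified residues are retained but never pruned or renamed.
- The identity-matrix convention and the affine rule disagree on the raw
  binary table (see above); the binary definition is authoritative.
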