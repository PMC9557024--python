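# Methods

## Scope and model

`nsalign` compares two single-chain macromolecular structures (protein, RNA
or DNA) by searching for a residue-level correspondence and a rigid-body
superposition that jointly maximize the TM-score

TM = (1/L) Σᵢ 1 / (1 + (dᵢ/d₀)²),

where the sum runs over the L_ali aligned unit pairs, dᵢ is the distance of
pair i under the superposition, and L is the length of the normalizing
chain. Each comparison reports two TM-scores (normalized by either chain,
each with its own d₀); the search itself optimizes the score normalized by
the shorter chain. The distance scale d₀ is

- protein: 1.24·(L−15)^{1/3} − 1.8 for L > 21, else 0.5;
- nucleic: 0.6·(L−0.5)^{1/2} − 2.5 for L ≥ 30, else a step table
  (0.7 for 24–29, 0.6 for 20–23, 0.5 for 16–19, 0.4 for 12–15, 0.3 for ≤ 11).

TM ≥ 0.5 (protein) or ≥ 0.45 (RNA) is annotated as a significant shared
topology. One alignment unit is one Cα (amino acids) or one C3′
(nucleotides) by default; under the `PC4'` convention each nucleotide
contributes two units (P first, then C4′, preserving backbone order; a
5′-terminal nucleotide without P contributes only C4′). That convention is
applied automatically when a protein is aligned against a nucleic acid,
because adjacent P–C4′ spacing is close to the ~3.8 Å Cα–Cα spacing; for a
`PC4'` chain the unit count (2 per nucleotide) is also the normalizing
length, scored with the nucleic d₀.

## TM-optimal superposition of a fixed alignment

Maximizing TM over rigid motions is not solvable in closed form (unlike
RMSD), so the engine enumerates contiguous windows over the aligned-pair
list ordered by chain-A index, at lengths L_ali, ⌈L_ali/2⌉, ⌈L_ali/4⌉, …, 4
(every start offset, stride 1). Each window is Kabsch-fitted (SVD with the
determinant correction, so the rotation is always proper; N = 1 falls back
to a translation, N = 2 to a segment-direction alignment) and the full
alignment is scored under the candidate transform. From the best candidate
a greedy refinement re-fits on the pairs within a distance cutoff
(max(d₀, 4.5 Å), widened by 1.5× whenever fewer than 3 pairs survive) until
the selected subset repeats, keeping the best TM ever seen. The refinement
is an addition over pure window enumeration and can be disabled
(`refine_superposition=False`); the contract is only that the result is at
least as good as the best single window.

## Sequential (SQ) mode

Five seed alignments: (1) the best gapless offset; (2) NW on a
secondary-structure match matrix (+1 same state, 0 otherwise); (3) NW on the
average of that matrix and the distance matrix implied by the best gapless
superposition; (4) the best fragment-pair Kabsch fit at lengths L/2 and L/3
slid over both chains (stride L/10), converted to a full NW alignment under
that transform; (5) the same with fragment length 4 at a coarser stride.
Candidate fragment fits are ranked by the TM of the gapless extension of
the fragment diagonal, and gapless offsets are ranked after one
outlier-trimmed refit, which keeps a few far pairs from tilting the
evaluation away from a good core.

Each seed is iterated to convergence: TM-optimal superposition of the
current alignment → residue-level score matrix 1/(1+(d/d₀)²) → NW with gap
penalty −0.6 → repeat, stopping when a pair set repeats or after 30
iterations; the best-TM state ever visited across all seeds is returned
(NW steps may decrease TM, so the last iterate is not necessarily best).

The NW dynamic program penalizes internal gaps linearly and leaves end gaps
free (zero first row/column; free moves along the last row/column). The
free-end-gap convention is what structure alignment needs — a fully global
gap model would punish a circularly permuted half-chain for its overhangs
more than aligning junk — and ties during traceback always prefer the
diagonal, then the vertical, then the horizontal move, so the whole mode is
deterministic. All reported SQ pairs are kept (no distance filter).

## Fully non-sequential (fNS) mode

For every residue i, its neighborhood fragment is the K = 5 spatially
nearest residues including i, ordered by distance (distances rounded to
10⁻⁶ Å so geometric ties break deterministically toward the lower index).
The initial similarity of residues i∈A, j∈B superposes fragment(i) onto
fragment(j) rank-to-rank by a batched Kabsch fit and scores
1/(1+(d_K/d₀)²) on the post-fit separation of the two rank-K members. Note
this fragment score is invariant to any global rigid motion of either
chain, which is why subsequent iterations rescore with the point-distance
matrix under the current global superposition instead (a
`fns_iteration_matrix="fragment"` switch keeps the initial matrix static
for comparison).

Assignments come from an Enhanced Greedy Search: a greedy stage repeatedly
takes the highest remaining matrix entry above a floor (default 0; ties to
the lowest row, then column) and deletes its row and column; a swap stage
then improves the assignment by best-improvement local search. The swap
neighborhood is pairwise partner exchanges plus reassignments to unassigned
rows/columns — implemented by zero-padding the matrix to a square so
reassignments become exchanges with zero-scoring dummy partners — and,
whenever no pairwise exchange improves, 3-cycle rotations. The 3-cycle
moves close the gap to the exhaustive optimum on all matrices with min
side ≤ 3 (pairwise exchanges alone provably admit local optima there) and
are scanned in chunks to bound memory. No randomness is used anywhere;
every tie breaks toward the lowest index.

fNS iterates superposition → point-distance matrix → EGS like the SQ loop.
Before reporting, assigned pairs farther than 8 Å (configurable) under the
final transform are dropped and the superposition re-fitted on the kept
pairs — but only when this does not lower the short-normalized TM, since
far pairs still contribute small positive score; this keeps the reported
score consistent with the returned pairs and never below the unfiltered
search result.

## Semi-non-sequential (sNS) mode

sNS seeds from the SQ result and iterates superposition → NW → the EGS swap
stage, where an exchange is vetoed unless, afterwards, the aligned partners
of every secondary-structure element (in either chain) are strictly
monotonic in sequence order. Because free-end-gap NW matches essentially
every residue rather than pay internal gaps, NW pairs whose similarity
falls below the score at the 8 Å filter distance are treated as unassigned
before the swap stage; otherwise those junk matches would pin both partners
and veto every element-crossing move. The SQ seed is the first state
evaluated, so the sNS TM never falls below the SQ TM on the same pair.
Within a single rigid superposition only mutually consistent element blocks
can be crossed; a two-element chain whose swap ranges cut through element
interiors is recoverable only by fNS, by construction.

## Secondary structure

Proteins: for each interior residue i the six Cα distances among residues
i−2…i+2 (d13, d14, d15, d24, d25, d35) are compared with reference values —
helix if max deviation from (5.45, 5.18, 6.37, 5.45, 5.18, 5.45) < 2.1 Å,
else strand if max deviation from (6.1, 10.4, 13, 6.1, 10.4, 6.1) < 1.42 Å,
else turn if d15 < 8 Å, else coil. Helix is tested first and therefore wins
any overlap. The two residues at each terminus lack a full window and are
assigned coil. Elements (for the sNS constraint) are maximal runs of ≥ 3
identical helix/strand states.

Nucleic acids: candidate pairs need (a) C3′–C3′ distance in [12.5, 15.0] Å,
(b) G:C, G:U or A:U complementarity (T read as U for DNA), and (c) a
stacked neighbour — (i−1, j+1) or (i+1, j−1) must also satisfy (a)+(b) —
which excludes singleton pairs. Each nucleotide keeps at most one partner;
conflicts resolve to the pair closest to the 13.75 Å window midpoint, then
to the lowest index. States are unpaired / paired-downstream /
paired-upstream; elements are runs of ≥ 2 consecutive paired states.

## Evaluation utilities

Structure overlap SO = 100 · |{dᵢ < 3.5 Å}| / min(L_A, L_B) (strict
inequality). EQR is the number of aligned pairs shared with a reference
alignment; agreement = 100·EQR/|reference|. ROC curves call a pair positive
at cutoff c when its score is ≥ c (or ≤ c under the `ascending` flag for
scores where lower means more similar); AUROC is the trapezoid area, and
the implementation is cross-checked against scikit-learn in the tests. The
sequence-identity statistic used to stratify benchmarks by homology is the
number of identical residues in the *sequential* alignment divided by the
shorter chain length, regardless of which mode is being benchmarked; the
per-report `seq_identity` field is instead identical residues over L_ali.
The batch runner records per-pair failures in an error column rather than
aborting.

## Synthetic data

The fixture generator concatenates parametric elements: α-helix (rise
1.5 Å, radius 2.3 Å, 100°/residue), extended zigzag strand (3.3 Å axial
advance, alternating ±1 Å offset), random-walk coil at 3.8 Å steps, and an
antiparallel nucleic-acid duplex stand-in (two straight strands 13.75 Å
apart, 5.5 Å intra-strand spacing, complementary random sequence). Element
parameters were chosen to satisfy the secondary-structure thresholds by
construction, and the duplex satisfies the pairing rules geometrically; it
is not a physically accurate A-form model, and none of the fixtures carry
side chains, packing constraints or realistic loop geometry. Derived
fixtures (rigid noisy copies, circular permutants, fragment swaps, permuted
helix bundles) carry exact ground-truth correspondences so recovery can be
scored, and every generator is a pure function of its spec and seed.

Recovery fixtures carry 0.05 Å coordinate noise. This is an identifiability
requirement, not a tuning knob: a noiseless parametric helix is congruent
with its own one-residue shift, so every shifted correspondence of a
permuted copy scores exactly 1 and a "true register" does not exist
geometrically. The noisy rigid-copy regime uses σ = 0.3 Å, roughly
crystallographic coordinate precision. Test problem sizes (60-residue
chains, 6-fold benchmark with 3 structures per fold) were chosen so the
full suite runs in seconds while leaving every code path exercised.

What passing these tests shows — and does not show: the engine provably
matches exhaustive oracles on small alignment/assignment problems, conforms
to the secondary-structure rules verbatim, and recovers planted
rearrangements on idealized geometry. Real structures add conformational
variability, missing atoms, and non-ideal secondary structure; performance
there depends on the same heuristics but is not certified by this suite.

## Numerical and design choices

- Internal residue indexing is 0-based and contiguous in file order; author
  numbering is kept as labels only. Only the first model of multi-model
  files is read unless another is requested. Altlocs resolve to the highest
  occupancy (ties: first in file); waters are dropped; modified residues
  with the representative atom (e.g. MSE) are kept. Chains mixing amino
  acids and nucleotides raise an error.
- Convergence of every iterative mode is exact repetition of the pair set,
  capped at 30 iterations; with best-ever tracking this guarantees
  termination without harming the result.
- All modes are deterministic: no RNG anywhere in the alignment path, all
  ties broken toward the lowest index, identical inputs give identical
  bytes.
- The significance annotation uses the nucleic cutoff (0.45) whenever
  either chain is nucleic, applied to the TM normalized by the shorter
  chain.
- Known limitations: no flexible/hinge alignment (a single rigid transform
  per comparison), no multi-chain complexes, no affine gap model, no
  statistical significance model beyond the fixed TM cutoffs.
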