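# Methods

This note documents the models implemented in `protpeel`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic fixtures do and do not establish.

## Input model

All computation runs on a cleaned, single-chain, Cα-only view of the
structure.  Cleaning removes heteroatom records, residues whose name is
not one of the 20 standard amino acids (deliberately including MSE and
other common modifications — they are removed, not remapped), and residues
carrying insertion codes; survivors are renumbered contiguously from 1
while the author numbering is retained for reporting.  Alternate locations
are resolved to the highest-occupancy Cα (ties: alphabetically first
alt-loc); residues without a Cα cannot enter the contact map and are
dropped with a warning.  Only one model of a multi-model file is read
(default: the first).  All residue intervals are 1-based and inclusive.

## Contact-probability map

The shared input of every later stage is the logistic transform

    p_ij = 1 / (1 + exp((d_ij − d0) / δ))

of the Cα–Cα distance d_ij, with p = 0.5 at d0 and soft shoulder δ.  The
smooth transform avoids the artifacts of a hard contact cutoff.  Defaults
are d0 = 8.0 Å (the conventional Cα contact midpoint) and δ = 1.5 Å;
both are configuration, echoed in output metadata, and were fixed before
any benchmarking.  "Contact mass" of a residue set is Σ_{i<j} p_ij over
pairs inside it; between disjoint sets it is Σ p_ij across.  Masses are
additive, so every statistic below conserves total mass under any
partition of the chain (tested to machine precision).

A *non-local* view zeroes pairs with sequence separation < 3; it feeds
the Compaction Index, the quality step function and the pseudo-energy,
where backbone-adjacent contacts would otherwise dominate.

## Peeling into Protein Units

A segment is split after positions c (one cut) or c1 < c2 (two cuts),
yielding sub-segments with intra masses I_k and total cross mass X.  The
partition index

    PI = (G − X²) / (G + X²),    G = (∏_k I_k)^(2/m)

is bounded in [−1, 1], scale-free, and equals 1 exactly when the
sub-segments are internally connected but fully decoupled.  The split scan
is exhaustive over all admissible cut sets (every sub-segment must reach
`min_pu_size`, default 15 residues — PUs are of intermediate size between
secondary structures and domains); ties break toward fewer cuts, then
leftmost positions, so peeling is reproducible bit for bit.  Prefix sums
over the contact matrix make each candidate O(1); an independent
brute-force enumeration (direct sub-matrix sums) serves as the test
oracle.

**Stopping rule.**  A split is accepted only when the best cut leaves its
sub-segments nearly decoupled: X²/G ≤ 0.05, i.e. the squared cross mass is
at most 5 % of the geometric mean of the intra-mass product (equivalently
PI ≥ 0.905).  A threshold on raw PI does not work: on realistic decaying
contact maps even a cut through the middle of a compact globule scores
PI ≈ 0.8, because G grows quadratically with segment mass while X² stays
bounded — raw-PI thresholds near 0 never stop the recursion.  The
coupling-ratio form asks the scale-free question directly.

**Double cuts are scanned but never chosen.**  For any 2-cut, the cross
mass is at least that of the better flanking 1-cut while G shrinks
(AM–GM), so under this PI a single cut always dominates.  The 2-cut scan
is retained for interface completeness and oracle coverage; central,
sequence-discontinuous units emerge at the assembly stage instead, where
non-adjacent PUs may merge into one domain.

Peeling is greedy and global: at each iteration the frontier unit whose
best split has the highest PI is split, and the new frontier is recorded
as the next level, until nothing is splittable or `max_pus` (default 16)
units exist.  Low levels hold few, long units; the last level holds the
terminal PUs used for assembly.  Each unit carries its Compaction Index

    CI = intra non-local mass / (intra non-local mass + non-local mass to the rest)

(1 = structurally independent; 0 when the unit has no non-local mass).

## Domain assembly and alternative partitions

Domains are unions of terminal PUs.  An agglomerative beam search starts
from the all-singleton partition; successor states (all pairwise domain
merges) are ranked by separation

    S(A, B) = X(A,B) / sqrt(I(A) · I(B))

descending (high S = strongly contacting units = good merge), ties by the
compactness C = I/|U| of the merged domain, then by smallest PU index.
The top `beam_width` (default 3) states survive per depth; every generated
state from |PUs| domains down to 1 is recorded, deduplicated by residue
sets, and scored.  Beam rank 1 reproduces the pure greedy path, so the
optimal trajectory is never lost; with unbounded beam the recorded states
are exactly the reachable set-partitions (tested against brute-force
enumeration for ≤ 5 PUs).

**Quality.**  A partition is graded 1–5 by a step function over two
scale-free ratios computed on the non-local map: ρ = inter-domain mass /
total chain mass (lower = better separated) and κ = min domain compactness
/ whole-chain compactness (higher = every domain at least chain-dense).
Steps: quality 5 at (ρ ≤ 0.03, κ ≥ 0.9), 4 at (0.06, 0.8), 3 at (0.10,
0.7), 2 at (0.15, 0.6), else 1; quality ≥ 2 is the acceptance range.  Both
ratios deliberately use the non-local map: the two or three
backbone-adjacent pairs that straddle *any* cut contribute ≈ 2.5 mass
regardless of where the cut falls, and would otherwise penalize every
multi-domain partition by a constant.  A single-domain partition is
ρ = 0, κ = 1, quality 5 by construction — the trivial decomposition is
always valid, which keeps the A-index of genuinely single-domain proteins
small (few partitions) rather than zero.  All constants are configuration
echoed in output, fixed a priori; they are calibrated only in the sense of
being round numbers on [0, 1] scales.

**Optimal partition.**  Among acceptable partitions: (i) most domains,
(ii) then highest mean domain compactness, (iii) then highest quality,
then deterministic order.  If nothing is acceptable the single-domain
partition is returned with a warning (unreachable in practice, since the
single-domain partition is always quality 5).

**A-index.**  The largest A such that at least A partitions have quality
≥ A — an h-index over the quality multiset.  Low values are neither good
nor bad: few high-quality partitions and many poor ones both give a low
A-index.

**Junctions.**  Boundary k (between residues k and k+1, termini excluded)
is a junction of partition p when k separates two domains or is an
internal extremity of a PU used to build p's domains (PU extremities can
be disabled by flag, since with terminal-PU assembly every partition uses
every PU and extremity junctions then have frequency 1 by construction).
Count = number of partitions containing the junction, frequency =
count/N_d, weight = Σ (quality/5)/N_d over containing partitions — so
weight ≤ frequency with equality exactly when every containing partition
has quality 5.

## Pseudo-energy, decoys, Z-score, AUL

A substructure's pseudo-energy is E = −Σ log-odds(a_i, a_j) over residue
pairs within it that have sequence separation ≥ 3 and Cα distance ≤ 8 Å.
Because such scores grow with size, E is standardized against decoys that
permute the unit's residue labels uniformly at random over fixed
coordinates (default 2000 decoys, fully seeded): Z = (E − μ)/σ with μ, σ
the decoy sample statistics.  The decoy distribution is not assumed
normal, so the one-sided probability that a random sequence scores as well
is bounded by Chebyshev's inequality, reported as the Autonomous Unit
Likelihood AUL = 100·(1 − 1/Z²) % for Z ≤ −1 and 0 % otherwise (Z = −2 →
75 %, Z = −4 → 93.75 %, reported as 94 %).  Units whose decoy energies
have zero spread (homopolymers, or units with no qualifying contacts) are
flagged degenerate and report Z and AUL as "n/a" — never 0 %, which would
conflate "no signal" with "not native-like".

The bundled 20×20 propensity table is a synthetic surface, log-odds(a,b) =
0.02·h(a)·h(b) on Kyte–Doolittle hydropathies: hydrophobic pairs score
favorably, mixed pairs unfavorably.  It is a placeholder with the right
symmetry and sign structure, not a trained statistical potential; absolute
Z-scores and AULs on real proteins should not be interpreted against
published numbers obtained with trained potentials.  The decoy/Z/AUL
machinery itself is exact and table-independent, and any 20×20
whitespace-delimited table (residue order ACDEFGHIKLMNPQRSTVWY) can be
dropped in.

## Secondary structure

Annotation is report-only — it never influences peeling or assembly.  The
canonical source is a DSSP output file, reduced 8→3 as H,G,I → H; E,B → E;
S,T,C (and blank) → C, aligned to the cleaned structure by original
residue number (missing residues → C).  Without a DSSP file a deliberately
crude Cα-geometry heuristic is used and labelled "approximate" in the
output metadata: runs of ≥ 4 windows with d(i, i+3) ∈ [4.5, 6.0] Å mark
helix over the covered residues, runs of ≥ 3 windows with d(i, i+2) ≥
6.4 Å mark strand, helix wins conflicts, everything else is coil; chains
shorter than 5 residues are all-coil.

## Synthetic fixtures

The generator emulates the one feature of real proteins that domain
decomposition actually keys on: contrast between dense intra-unit and
sparse inter-unit contacts.  Globules are self-avoiding random walks
(3.8 Å steps, pairwise clash floor 3.5 Å) confined to 10 Å spheres whose
centers sit ≥ 3 radii apart; linkers are near-straight 3.8 Å-step paths;
sequences are uniform over the 20 amino acids.  Ground truth (segment
boundaries, linker midpoints) is returned with every structure.  Default
study conditions for boundary-recovery checks: two 30-residue globules, a
5-residue linker, 20 seeds.

What fixtures do *not* emulate: secondary-structure content, side chains,
realistic packing density gradients, evolved sequence signal (so decoy
Z-scores on fixtures hover near 0 and AUL is 0 %), and discontinuous
domains arising from chain re-entry.  Passing the fixture suite therefore
demonstrates correctness of the algorithms on structures with known
contact topology, not benchmark accuracy on curated domain databases.

## Numerical choices and limitations

- Split-candidate and merge tie-breaks are fully deterministic; runs are
  byte-identical given the same configuration and seed.  Per-unit decoy
  seeds are derived from the run seed and the unit's residue interval, so
  results do not depend on assessment order.
- Near-ties in the split scan within 1e-12 of PI are treated as exact ties
  (first candidate in deterministic order wins), keeping the prefix-sum
  path and the direct-summation oracle in exact agreement.
- Decoy spread below 1e-10 (relative) is clamped to zero: permutations of
  identical labels differ only by float summation order.
- The beam search bounds compute on proteins that peel into many PUs; with
  default width 3 it can miss exotic partitions a full enumeration would
  find.  Widening the beam only adds partitions.
- Peeling only produces contiguous units; sequence-discontinuous
  substructures appear first at the assembly stage.
- The quality thresholds, logistic parameters and the coupling threshold
  are package defaults, configurable and echoed in every output; none is a
  published constant.
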