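# Methods

## Model

A secondary structure over an N-nucleotide RNA is a set of base pairs
(i, j), 1 ≤ i < j ≤ N, in which no nucleotide pairs twice, no two pairs
cross (pseudoknots are out of scope), allowed pair types are AU, UA, CG,
GC, GU, UG (`N` never pairs), and every hairpin loop contains at least
`min_hairpin` unpaired nucleotides (default 3, i.e. j − i ≥ 4). Indices
are 1-based with closed intervals throughout.

Free energies follow a nearest-neighbor loop decomposition: stacking
terms for adjacent pairs, initiation tables for hairpin, bulge and
internal loops, a Ninio asymmetry penalty for internal loops, an affine
multiloop model `a + b·branches + c·unpaired`, and a terminal penalty for
AU/UA/GU/UG pairs charged once per non-stack loop a pair borders (so a
lonely AU pair closing a hairpin from the exterior pays it twice — once
to the hairpin, once to the exterior loop). The exterior loop otherwise
contributes zero. Dangling ends, coaxial stacking and temperature
rescaling are deliberately excluded: they would not change any structural
(combinatorial, constraint or equivalence) property the package asserts,
and the parameter set makes no claim of reproducing any published table
bit-exactly. Structure evaluation (`eval_structure`) walks the loop tree
of a complete structure and is the energy oracle for everything else.

### Numeric representation

All internal energies are integers in tenths of a kcal/mol. This makes
the window comparison `ΔG(P) + ΔG(σ) ≤ MFE + W` exact: whether a
structure sits inside the window can never depend on float accumulation
order. Conversion to kcal/mol happens only at the API boundary. The
"infinite" energy is a large sentinel integer; saturating addition
prevents overflow into nonsense.

### Parameter set

The shipped default (`params/default.par`) is a compact Turner-style
table: stacks for all 36 ordered pair-type combinations, hairpin
initiation 5.4–7.7 kcal/mol (lengths 3–30), bulge 2.8–6.1 (1–30),
internal 1.1–3.7 (2–30), multiloop a = 3.4, b = 0.4, c = 0.0, terminal
AU/GU penalty 0.5, Ninio 0.6 per unpaired-length unit capped at 3.0.
Loops beyond length 30 extend as `table[30] + 1.75·RT·ln(L/30)` with
RT at 310.15 K. Values were fixed once, before any end-to-end check, as
typical published magnitudes; the file dialect (plain-text blocks in
kcal/mol) accepts user tables.

## Enumeration

The fill step computes, under hard constraints, the standard Zuker
tables: `V[i][j]` (minimum energy given (i, j) paired), `W[i][j]` (any
structure on [i, j]), and multiloop segment tables `M` (≥ 1 branch) and
`M1` (exactly one branch anchored at the left edge); a multiloop closed
by (i, j) decomposes as `a + b + M[i+1][u] + M1[u+1][j-1]`, which
guarantees at least three branches counting the closing pair and makes
every decomposition unique. Interior loops are **not** capped at the
conventional 30 unpaired nucleotides: the enumerator, the counting DP,
the evaluator and the brute-force oracle must all describe the same
structure universe for the exact-equality tests to be meaningful, and at
the problem sizes this package targets the O(N⁴) fill is negligible.

Backtracking states carry intervals tagged with the recursion they refine
against (W, V, M, M1). This labeled-interval formulation — rather than
the minimal "intervals + pairs" sketch — is what makes the energy of the
determined portion exact at every step and the table bound admissible, so
the emitted set is exactly the window set, each structure once. The
refinement order is fixed (tail interval; unpaired-3'-end child first,
then pairing partners ascending; within V: hairpin, then inner pairs,
then multiloop splits), making runs reproducible and serial/parallel
outputs comparable. A child is discarded at creation when any remaining
interval becomes uncompletable (infinite bound), which also handles
constraint-unsatisfiable regions in the purely combinatorial
(infinite-window) mode.

The window threshold is taken relative to the fill-step MFE. Hard
constraints enter the fill; the context-dependent probing rule does not —
it prunes only during backtracking, so the tables remain lower bounds
(ignoring a constraint can only lower a minimum). Consequently, under
probing constraints the threshold is measured from the *unfiltered*
constrained MFE; this mirrors the original structure of the method, where
the probing filter lives purely in the refinement step.

### Lonely pairs

Classic implementations discourage isolated pairs with an energy penalty,
which a window wider than the penalty silently defeats. The
energy-independent variant here prunes structurally: when the interior of
pair (i, j) is resolved without the stacked pair (i+1, j−1), and
(i−1, j+1) is not fixed either, no remaining interval can ever rescue
(i, j), so the branch is discarded. Because of the refinement order the
outer neighbor of a pair is always decided before its interior, which
reduces the general "could any interval still rescue this pair" test to a
single check at interior-resolution time. The general predicate
(`lonely_pair_prunable`) is still exposed and property-tested.

### Context-dependent probing

A probed nucleotide in a Watson-Crick pair flanked on both sides by
Watson-Crick pairs is inadmissible; GU pairs and GU neighbors, helix
ends, and loop/bulge-adjacent pairs are fine. Since the inner neighbor of
a pair is decided after the pair itself, the rule is enforced
incrementally: each pair proposal is checked both as a potential victim
(its outer neighbor is already known) and as the move that completes the
Watson-Crick sandwich around an earlier probed pair — the proposal, not
the earlier pair, is rejected. A post-hoc validator
(`structure_satisfies`) re-checks complete structures in tests.
Sequence-terminal pairs count as helix ends (no outer pair can exist).
Probed marks never force anything: every structure legal under the rule
is kept, which is why probing marks can never yield fewer structures than
hard unpaired marks at the same positions.

### Counting

`count_structures` is an independent dynamic program over the same
structural rules with Python big integers (counts pass 64-bit range well
before N = 60). The DP state is (interval, type of the adjacent enclosing
pair, branch-limit flag): the adjacency type lets the probing rule be
counted exactly (a probed WC pair under a WC outer neighbor contributes
its interior count *minus* the interiors that WC-stack immediately
inside), and the branch-limit flag implements the no-multibranch
restriction. Counting deliberately ignores lonely-pair pruning: it
matches the enumerator's leaf count with an infinite window and no
lonely-pair flag, which is the convention under which the design 14-mer
has exactly 119 structures (open chain included).

### Low-memory mode

Standard refinement materializes all children of a state before pushing
them, so the stack grows with depth × branching before the first leaf.
The low-memory mode explores depth-first with one lazy child iterator per
tree level: a single branch per node is in memory, bounding retained
state by the refinement depth, which is at most one frame per nucleotide.
Output sets are identical; only emission order differs.

## Parallel driver

One master (the calling process) and `n_workers` worker processes share
the refinement stack by message passing: workers send `need_work` when
idle and `share_states` when their stack exceeds `share_threshold`
(shedding the oldest, shallowest half — shallow states carry the most
remaining work); the master answers `grant_state` (one state) or
`terminate`, and refines states itself when no messages are pending.
Workers recompute the fill tables locally from the run parameters, so
serialized states (a compact JSON round-trip format) are the only payload
on the channel. Completed structures go to per-worker spill files merged
at the end. Termination requires an empty master stack and all workers
idle; since each per-worker channel is FIFO, no share can still be in
flight at that point. Each state is refined exactly once across all
processes (asserted by counter accounting in tests), so the merged output
equals the serial enumeration for every worker count and threshold. A
worker exception is forwarded to the master and aborts the run; partial
results are never returned silently. Wall-clock speedup is hardware- and
scale-dependent and is not asserted anywhere.

## Synthetic data

Two deterministic fixture generators stand in for external data:
`random_seq` (uniform ACGU under a seed, capped at brute-force-verifiable
lengths) and `planted_probing`, a designed 16-nt hairpin whose six-pair
helix instantiates every probing context at known positions — helix end,
loop-adjacent, GU pair, GU-adjacent, and one Watson-Crick pair sandwiched
between two Watson-Crick pairs (the single inadmissible case) — with
expected admissibility recorded in the fixture. These fixtures emulate
the *logic* of probing data, not its noise: real reactivities are
continuous, error-prone and sometimes contradictory, so passing tests
demonstrate correct constraint semantics, not robustness to noisy
experimental input. Likewise uniform random sequences probe correctness,
not the base-composition biases of natural RNAs.

## Problem sizes and verification

Every exactness claim is verified two ways at small scale: the enumerator
against brute-force enumerate-evaluate-filter (hundreds of random 8–16-mers,
windows from 0 to infinite), the counting DP against brute force under
every constraint/option combination and against an independent
reference tool on the combinatorial set, and the parallel driver against
the serial enumerator over worker counts 1–8 and thresholds 1–1000. The
test and acceptance workloads use 8–28-nt sequences (counting only at
42 nt), sizes at which the complete structure space is independently
checkable; the algorithms themselves carry no small-N assumptions beyond
the brute-force oracle's explicit guard.

## Known limitations

* Energies are model-faithful but not table-exact against any published
  parameter set; absolute free energies of natural RNAs will differ.
* No pseudoknots, partition function, base-pair probabilities or
  Boltzmann sampling.
* The probing rule is a boolean context filter; quantitative
  (reactivity-valued) soft constraints are out of scope.
* The helix filter defines a mismatch as a single 1×1 internal loop;
  bulges and larger loops always terminate a helix. The definition is
  isolated behind `find_helices` so an alternative reading can be
  swapped in.
* The parallel backend is single-machine process-based; the message
  contract is transport-agnostic but no cluster (MPI) transport ships.
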