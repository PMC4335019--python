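# subfold

Combinatorially complete enumeration of RNA secondary structures within a
free-energy window.

A single minimum-free-energy (MFE) prediction is often a poor summary of an
RNA's folding landscape: many very different structures can lie within a
few kcal/mol of the minimum, and experimental probing data frequently
narrow the conformational space without ever defining one unique fold.
`subfold` addresses this by enumerating *every* non-pseudoknotted secondary
structure of a sequence whose free energy lies within a chosen window above
the MFE — not a sample, the complete set — so that hypotheses about the
landscape ("no structure with these helices exists", "probing data still
admit millions of folds") can be tested exactly. It is aimed at structural
bioinformaticians studying folding landscapes, probing-data integration,
and encapsidated viral RNA.

## Method

The enumerator is a stack-based backtracking (Wuchty-style) search over
partially determined structures. A state is a set of fixed pairs `P` plus
a list of unevaluated intervals `σ`; the root holds the single interval
`[1, n]` and no pairs. Refining a state removes one interval and produces
children — the 3'-most nucleotide unpaired, or paired to each admissible
partner — whose energies split into an exactly known part ΔG(P) and a
lower bound ΔG(σ) taken from Zuker dynamic-programming tables (`V`, `W`
and multiloop arrays) filled once in O(N³)–O(N⁴) time. A child survives
only if `ΔG(P) + ΔG(σ) ≤ MFE + W`; every leaf (empty σ) is a complete
structure, emitted exactly once. Because the bound is admissible, the
output is the exact set of structures in the window.

On top of the core search:

* **Exact counting.** A separate big-integer dynamic program counts the
  combinatorial structure space (infinite window) without enumerating it.
  The 1.8^N rule of thumb estimates the same quantity analytically.
* **No lonely pairs, energy-independent.** Instead of an energy penalty
  (which a wide window can out-vote), a branch is discarded the moment an
  isolated pair can no longer acquire a stacked neighbor from any
  remaining interval.
* **Constraints.** Hard single-strand marks (`x`), forced pairs
  (`(`/`)`), a maximum pair span, and context-dependent probing marks
  (`m`): a chemically modified nucleotide may pair at a helix end, next
  to a loop, bulge or GU pair, or in a GU pair — but never as a
  Watson-Crick pair flanked on both sides by Watson-Crick pairs.
* **Optional multibranch loops.** Disabling multiloops forces every
  closed pair to enclose at most one branch (a series of stem-loops, the
  shape expected from cotranscriptional folding), while the exterior loop
  may still hold many stems.
* **Helix filter.** Completed structures can be required to contain at
  least *k* helices of at least *l* pairs with at most *m* 1×1
  mismatches each — a global shape constraint from crystallography or
  cryo-EM of encapsidated viral RNA.
* **Parallel driver.** A master–worker scheme shares the refinement
  stack over worker processes with dynamic load balancing; the merged
  output is provably identical to the serial run.
* **Landscape metrics.** Base-pair distance (symmetric difference of
  pair sets) and ensemble summaries (count, energy span, max/mean
  distance to the MFE structure).

Free energies use a compact, self-contained nearest-neighbor parameter
set (stacking for all six pair types, loop tables with logarithmic
extension, affine multiloops, terminal AU/GU penalties); the full table
ships as a documented plain-text file
(`src/subfold/params/default.par`) and custom tables in the same dialect
can be loaded with `--params`.

## Worked example

The 14-mer `GCUCUAAAAGAGAG` is designed so that its hairpin instantiates
every probing-constraint context. Enumerating everything within
2 kcal/mol of the MFE:

```text
$ subfold fold GCUCUAAAAGAGAG --window 2.0 --sorted
> stdin
GCUCUAAAAGAGAG
.((((...)))).. -0.70
.((((.....)))) -0.40
.............. 0.00
.(((.....))).. 1.20
```

Four structures fall in the window: the MFE hairpin at −0.70 kcal/mol, a
shifted hairpin with a larger loop, the open chain at exactly 0, and a
shortened helix 1.2 kcal/mol above the minimum. With no window at all the
enumeration is purely combinatorial:

```text
$ subfold count GCUCUAAAAGAGAG
119
```

119 is the complete count of non-pseudoknotted structures for this
sequence (Watson-Crick + GU pairs, hairpin loops of at least three
nucleotides, open chain included). The `--estimate` flag prints the
1.8^N approximation instead, `subfold eval SEQ DOTBRACKET` evaluates one
structure, and `subfold distance A B` gives the base-pair distance
between two dot-brackets. `subfold fold --workers 4 --share-threshold 64`
runs the same enumeration in parallel with identical output.

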