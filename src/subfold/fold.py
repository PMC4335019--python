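"""Zuker fill step and exact structure counting.

``fill_matrices`` produces the dynamic-programming tables whose entries
are the minimum free energy achievable on each subsequence; during the
backtracking enumeration they serve as admissible lower bounds for the
unevaluated intervals of a partial structure. Four tables are kept
(1-based closed intervals, integer decikcal):

* ``V[i][j]`` — minimum energy on [i, j] given that (i, j) pairs,
* ``W[i][j]`` — minimum energy of any structure on [i, j] (exterior-like),
* ``M[i][j]`` — [i, j] as a multiloop segment holding >= 1 branch,
* ``M1[i][j]`` — [i, j] as a multiloop segment whose single branch starts
  at i (possibly followed by unpaired nucleotides).

``count_structures`` is an independent big-integer dynamic program over
the same structural rules with no energy model: it counts every structure
satisfying the pairing rules, the minimum hairpin loop and the constraint
set (including the context-dependent probing rule and the optional
no-multibranch restriction), open chain included.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from functools import lru_cache

from .constraints import ConstraintSet
from .energies import INF, EnergyParameters, loop_energy
from .errors import ValidationError
from .options import FoldOptions
from .structure import is_wc, normalize_sequence, pair_type


@dataclass
class FoldMatrices:
    """Fill tables for one (sequence, constraints, options) combination."""

    n: int
    V: list[list[int]]
    W: list[list[int]]
    M: list[list[int]]
    M1: list[list[int]]

    @property
    def mfe_deci(self) -> int:
        return self.W[1][self.n]

    @property
    def mfe(self) -> float:
        """Minimum free energy in kcal/mol (under hard constraints)."""
        if self.mfe_deci >= INF:
            raise ValidationError("constraints admit no structure at all")
        return self.mfe_deci / 10.0


def _add(*terms: int) -> int:
    """Saturating decikcal addition: any infinite term wins."""
    total = 0
    for t in terms:
        if t >= INF:
            return INF
        total += t
    return total


def fill_matrices(
    seq: str,
    params: EnergyParameters,
    constraints: ConstraintSet | None = None,
    options: FoldOptions | None = None,
) -> FoldMatrices:
    """Run the constrained Zuker fill; O(N^4) time, O(N^2) memory.

    Interior loops are not capped in size, so the tables describe exactly
    the same structure/energy universe as the evaluator and the
    enumerator. Hard constraints enter the fill; the context-dependent
    probing rule does not (it only prunes during backtracking), which
    keeps every table entry an admissible lower bound.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n < 1:
        raise ValidationError("empty sequence")
    cs = constraints if constraints is not None else ConstraintSet.empty(n)
    opts = options if options is not None else FoldOptions()
    cs.validate(min_hairpin=opts.min_hairpin)
    h = opts.min_hairpin

    # prefix counts of forced-paired positions for O(1) interval queries
    fp = [0] * (n + 1)
    for k in range(1, n + 1):
        fp[k] = fp[k - 1] + (1 if cs.forced_paired(k) else 0)

    def free(a: int, b: int) -> bool:
        """No forced-paired position inside [a, b]."""
        return a > b or fp[b] - fp[a - 1] == 0

    allowed = [[False] * (n + 2) for _ in range(n + 2)]
    au = [[0] * (n + 2) for _ in range(n + 2)]
    for i in range(1, n + 1):
        for j in range(i + h + 1, n + 1):
            if cs.pair_allowed_hard(seq, i, j, min_hairpin=h):
                allowed[i][j] = True
                au[i][j] = params.au_e(pair_type(seq, i, j))

    big = [[INF] * (n + 2) for _ in range(n + 2)]
    V = [row[:] for row in big]
    M = [row[:] for row in big]
    M1 = [row[:] for row in big]
    W = [[0] * (n + 2) for _ in range(n + 2)]

    for span in range(0, n):
        for i in range(1, n - span + 1):
            j = i + span

            if allowed[i][j]:
                best = params.hairpin_e(j - i - 1) + au[i][j] if free(i + 1, j - 1) else INF
                for p in range(i + 1, j - h - 1):
                    if not free(i + 1, p - 1):
                        break
                    for q in range(j - 1, p + h, -1):
                        if not free(q + 1, j - 1):
                            break
                        if allowed[p][q]:
                            cand = _add(loop_energy(params, seq, i, j, p, q), V[p][q])
                            if cand < best:
                                best = cand
                if not opts.no_multibranch:
                    close = params.multiloop_closing + params.multiloop_branch + au[i][j]
                    for u in range(i + 1, j - 1):
                        cand = _add(close, M[i + 1][u], M1[u + 1][j - 1])
                        if cand < best:
                            best = cand
                V[i][j] = best

            # multiloop segment tables (unused under no_multibranch)
            if not opts.no_multibranch:
                c = params.multiloop_unpaired
                m_best = _add(M[i][j - 1], c) if not cs.forced_paired(j) else INF
                m1_best = _add(M1[i][j - 1], c) if not cs.forced_paired(j) else INF
                if allowed[i][j] and V[i][j] < INF:
                    branch = _add(V[i][j], params.multiloop_branch, au[i][j])
                    m_best = min(m_best, branch)
                    m1_best = min(m1_best, branch)
                for k in range(i + 1, j - h):
                    if not allowed[k][j] or V[k][j] >= INF:
                        continue
                    branch = _add(V[k][j], params.multiloop_branch, au[k][j])
                    left = M[i][k - 1]
                    if free(i, k - 1):
                        left = min(left, c * (k - i))
                    m_best = min(m_best, _add(left, branch))
                M[i][j] = m_best
                M1[i][j] = m1_best

            w_best = W[i][j - 1] if not cs.forced_paired(j) else INF
            for k in range(i, j - h):
                if allowed[k][j] and V[k][j] < INF:
                    left = W[i][k - 1] if k > i else 0
                    w_best = min(w_best, _add(left, V[k][j], au[k][j]))
            W[i][j] = w_best

    return FoldMatrices(n=n, V=V, W=W, M=M, M1=M1)


# ---------------------------------------------------------------------------
# exact combinatorial counting

_OUTER_NONE, _OUTER_WC, _OUTER_GU = 0, 1, 2


def count_structures(
    seq: str,
    constraints: ConstraintSet | None = None,
    options: FoldOptions | None = None,
) -> int:
    """Exact number of structures satisfying pairing rules and constraints.

    Energy-free (equivalent to an infinite window with no lonely-pair
    pruning); the open chain counts. Exact integer arithmetic throughout,
    so counts beyond the 64-bit range are fine. The DP state carries the
    type of the adjacent enclosing pair so the context-dependent probing
    rule is counted exactly.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n < 1:
        raise ValidationError("empty sequence")
    cs = constraints if constraints is not None else ConstraintSet.empty(n)
    opts = options if options is not None else FoldOptions()
    cs.validate(min_hairpin=opts.min_hairpin)
    h = opts.min_hairpin
    probing = cs.has_probing()

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * n + 1000))

    def probed(i: int, j: int) -> bool:
        return cs.probed(i) or cs.probed(j)

    @lru_cache(maxsize=None)
    def inner(k: int, j: int, outer: int) -> int:
        """Count of interiors of pair (k, j), given the type of the
        enclosing pair adjacent to it (if any)."""
        wc = is_wc(seq, k, j)
        if probing and probed(k, j) and wc and outer == _OUTER_WC:
            return seg_excl_wc(k + 1, j - 1)
        return seg(k + 1, j - 1, _OUTER_WC if wc else _OUTER_GU, opts.no_multibranch)

    @lru_cache(maxsize=None)
    def seg_excl_wc(a: int, b: int) -> int:
        """Segment count excluding structures where (a, b) is a WC pair
        (the enclosing probed WC pair must keep a non-WC inner context)."""
        total = seg(a, b, _OUTER_WC, opts.no_multibranch)
        if cs.pair_allowed_hard(seq, a, b, min_hairpin=h) and is_wc(seq, a, b):
            total -= inner(a, b, _OUTER_WC)
        return total

    @lru_cache(maxsize=None)
    def seg(a: int, b: int, outer: int, limited: bool) -> int:
        """Structures on [a, b]; ``limited`` caps the segment at one branch."""
        if a > b:
            return 1
        total = 0
        if not cs.forced_paired(b):
            total += seg(a, b - 1, _OUTER_NONE, limited)
        for k in range(a, b - h):
            if not cs.pair_allowed_hard(seq, k, b, min_hairpin=h):
                continue
            if limited:
                if not cs.interval_unpairable(a, k - 1):
                    continue
                left = 1
            else:
                left = seg(a, k - 1, _OUTER_NONE, False) if k > a else 1
            if left:
                total += left * inner(k, b, outer if k == a else _OUTER_NONE)
        return total

    return seg(1, n, _OUTER_NONE, False)


def estimate_structure_count(n: int) -> float:
    """The 1.8**N rule-of-thumb estimate of the combinatorial count."""
    if n < 1:
        raise ValidationError("sequence length must be >= 1")
    return 1.8 ** n
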