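"""Complete suboptimal enumeration within an energy window.

The enumerator refines partial structures: a state is a list of
unevaluated intervals (sigma) plus a set of fixed pairs, with the energy
of the determined portion accumulated exactly and the remaining energy
bounded from below by the fill tables. A state whose sigma is empty is a
leaf — a completely determined secondary structure — and every structure
with energy <= MFE + window is reached exactly once.

Each interval carries the recursion it refines against:

* ``W`` — exterior-like segment [i, j]: either j is unpaired, or some
  (k, j) pairs, splitting off [i, k-1] and the closed interval (k, j);
* ``V`` — the interior of fixed pair (i, j): hairpin, stack/bulge/internal
  loop with one inner pair, or (unless disabled) a multiloop split;
* ``M`` / ``M1`` — multiloop segments (>= 1 branch / exactly one branch
  starting at the left edge).

Children are pruned when (a) their energy bound exceeds the window
threshold, (b) an interval can no longer be completed at all, (c) a
constraint (hard or context-dependent probing) forbids the proposed pair,
or (d) with ``no_lonely_pairs``, a fixed pair has permanently lost every
chance of acquiring a stacked neighbor. Pruning happens at child
creation, so the branch is discarded instead of ever entering the stack.

``brute_force_enumerate`` is an independent oracle for small sequences:
plain recursive enumeration of all non-crossing pair sets with no energy
model and no pruning heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

from .constraints import ConstraintSet, allow_pair, structure_satisfies
from .energies import INF, EnergyParameters, load_parameters, loop_energy
from .errors import EnumerationCapExceeded, ValidationError
from .fold import FoldMatrices, estimate_structure_count, fill_matrices
from .options import FoldOptions
from .structure import SecondaryStructure, normalize_sequence, pair_type


class SafetyCapWarning(UserWarning):
    """Projected structure count exceeds the configured safety cap."""


#: interval kinds
W, V, M, M1 = "W", "V", "M", "M1"


@dataclass(frozen=True)
class PartialState:
    """One node of the refinement tree.

    sigma: unevaluated closed intervals (i, j, kind), refined from the tail.
    pairs: fixed base pairs.
    dg_p: exact energy (decikcal) of the determined portion.
    dg_sigma: sum of fill-table lower bounds over sigma (decikcal).
    resume_cursor: child index to resume from (low-memory bookkeeping).
    """

    sigma: tuple[tuple[int, int, str], ...]
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    dg_p: int = 0
    dg_sigma: int = 0
    resume_cursor: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.sigma


def interval_bound(m: FoldMatrices, iv: tuple[int, int, str]) -> int:
    """Fill-table lower bound for the remaining energy of one interval."""
    i, j, kind = iv
    if kind == W:
        return m.W[i][j] if i <= j else 0
    if kind == V:
        return m.V[i][j]
    if kind == M:
        return m.M[i][j] if i <= j else INF
    if kind == M1:
        return m.M1[i][j] if i <= j else INF
    raise ValidationError(f"unknown interval kind {kind!r}")


def root_state(m: FoldMatrices) -> PartialState:
    return PartialState(sigma=((1, m.n, W),), dg_sigma=m.W[1][m.n])


def lonely_pair_prunable(
    s: PartialState,
    seq: str | None = None,
    cs: ConstraintSet | None = None,
    min_hairpin: int = 3,
) -> bool:
    """True when some fixed pair is irreversibly lonely.

    A pair (i, j) is lonely when neither (i+1, j-1) nor (i-1, j+1) is
    fixed; it is rescuable only while an unevaluated interval could still
    form the inner neighbor — its own interior interval, or a sigma
    interval spanning exactly [i+1, j-1]. Rescue is conservative-exact:
    interval membership plus pair-type legality, never energy.
    """
    if not s.pairs:
        return False
    spans = {(i, j) for i, j, kind in s.sigma}
    open_v = {(i, j) for i, j, kind in s.sigma if kind == V}
    for i, j in s.pairs:
        if (i + 1, j - 1) in s.pairs or (i - 1, j + 1) in s.pairs:
            continue
        inner = (i + 1, j - 1)
        formable = (i, j) in open_v or inner in spans
        if formable and seq is not None:
            legal = inner[1] - inner[0] >= min_hairpin + 1 and (
                cs or ConstraintSet.empty(len(seq))
            ).pair_allowed_hard(seq, *inner, min_hairpin=min_hairpin)
            formable = legal
        if not formable:
            return True
    return False


# ---------------------------------------------------------------------------
# refinement


def _iter_children(
    s: PartialState,
    m: FoldMatrices,
    seq: str,
    cs: ConstraintSet,
    opts: FoldOptions,
    params: EnergyParameters,
    threshold: int | None,
) -> Iterator[PartialState]:
    """Yield viable children of s in the fixed deterministic order."""
    h = opts.min_hairpin
    head, iv = s.sigma[:-1], s.sigma[-1]
    i, j, kind = iv
    base_sigma = s.dg_sigma - interval_bound(m, iv)
    pm = {}
    for a, b in s.pairs:
        pm[a], pm[b] = b, a

    def emit(new_ivs, add_pairs, dg_add):
        kept = []
        for iv2 in new_ivs:
            a, b2, k2 = iv2
            if k2 == W and a > b2:
                continue  # empty exterior segment: nothing left to decide
            if k2 in (M, M1) and a > b2:
                return None  # a multiloop segment must still hold a branch
            kept.append(iv2)
        new_ivs = tuple(kept)
        dg_sigma = base_sigma
        for iv2 in new_ivs:
            b = interval_bound(m, iv2)
            if b >= INF:
                return None
            dg_sigma += b
        dg_p = s.dg_p + dg_add
        if threshold is not None and dg_p + dg_sigma > threshold:
            return None
        return PartialState(
            sigma=head + new_ivs,
            pairs=s.pairs | set(add_pairs),
            dg_p=dg_p,
            dg_sigma=dg_sigma,
        )

    def au(a, b):
        return params.au_e(pair_type(seq, a, b))

    if kind == W:
        if not cs.forced_paired(j):
            child = emit(((i, j - 1, W),), (), 0)
            if child is not None:
                yield child
        for k in range(i, j - h):
            if cs.pair_allowed_hard(seq, k, j, min_hairpin=h) and allow_pair(k, j, pm, seq, cs):
                child = emit(((i, k - 1, W), (k, j, V)), ((k, j),), au(k, j))
                if child is not None:
                    yield child

    elif kind == V:
        outer_ok = pm.get(i - 1) == j + 1
        lp = opts.no_lonely_pairs and not outer_ok
        # hairpin
        if not lp and cs.interval_unpairable(i + 1, j - 1):
            child = emit((), (), params.hairpin_e(j - i - 1) + au(i, j))
            if child is not None:
                yield child
        # one inner pair: stack, bulge or internal loop
        for p in range(i + 1, j - h - 1):
            if not cs.interval_unpairable(i + 1, p - 1):
                break
            for q in range(j - 1, p + h, -1):
                if not cs.interval_unpairable(q + 1, j - 1):
                    break
                if lp and not (p == i + 1 and q == j - 1):
                    continue
                if cs.pair_allowed_hard(seq, p, q, min_hairpin=h) and allow_pair(p, q, pm, seq, cs):
                    child = emit(
                        ((p, q, V),), ((p, q),), loop_energy(params, seq, i, j, p, q)
                    )
                    if child is not None:
                        yield child
        # multiloop split
        if not opts.no_multibranch and not lp:
            dg_close = params.multiloop_closing + params.multiloop_branch + au(i, j)
            for u in range(i + 1, j - 1):
                child = emit(((i + 1, u, M), (u + 1, j - 1, M1)), (), dg_close)
                if child is not None:
                    yield child

    elif kind == M:
        c = params.multiloop_unpaired
        if not cs.forced_paired(j):
            child = emit(((i, j - 1, M),), (), c)
            if child is not None:
                yield child
        for k in range(i, j - h):
            if not (cs.pair_allowed_hard(seq, k, j, min_hairpin=h) and allow_pair(k, j, pm, seq, cs)):
                continue
            dg_branch = params.multiloop_branch + au(k, j)
            if cs.interval_unpairable(i, k - 1):  # all-unpaired left flank
                child = emit(((k, j, V),), ((k, j),), dg_branch + c * (k - i))
                if child is not None:
                    yield child
            if k > i:  # at least one more branch on the left
                child = emit(((i, k - 1, M), (k, j, V)), ((k, j),), dg_branch)
                if child is not None:
                    yield child

    elif kind == M1:
        c = params.multiloop_unpaired
        for k in range(i + h + 1, j + 1):
            if not cs.interval_unpairable(k + 1, j):
                continue  # a forced-paired position sits in the tail flank
            if cs.pair_allowed_hard(seq, i, k, min_hairpin=h) and allow_pair(i, k, pm, seq, cs):
                child = emit(
                    ((i, k, V),), ((i, k),), params.multiloop_branch + au(i, k) + c * (j - k)
                )
                if child is not None:
                    yield child
    else:  # pragma: no cover
        raise ValidationError(f"unknown interval kind {kind!r}")


def refine_state(
    s: PartialState,
    m: FoldMatrices,
    seq: str,
    cs: ConstraintSet,
    opts: FoldOptions,
    params: EnergyParameters,
    threshold: int | None = None,
) -> list[PartialState]:
    """Materialized children of a state (the lazy iterator drives the
    low-memory mode; this wrapper is the stack-refinement entry point)."""
    if s.is_leaf:
        raise ValidationError("cannot refine a leaf state")
    return list(_iter_children(s, m, seq, cs, opts, params, threshold))


# ---------------------------------------------------------------------------
# top-level enumeration


def _leaf_structure(s: PartialState, n: int) -> SecondaryStructure:
    return SecondaryStructure(n=n, pairs=s.pairs, energy=s.dg_p / 10.0)


def enumerate_suboptimal(
    seq: str,
    cs: ConstraintSet | None = None,
    opts: FoldOptions | None = None,
    params: EnergyParameters | None = None,
    matrices: FoldMatrices | None = None,
) -> Iterator[SecondaryStructure]:
    """Yield every structure with energy <= MFE + window, exactly once.

    With ``opts.window = None`` the enumeration is purely combinatorial.
    The helix filter (if any) is applied to completed structures only.
    ``opts.sort_output`` collects and orders by (energy, dot-bracket);
    otherwise order follows the deterministic refinement order.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    cs = cs if cs is not None else ConstraintSet.empty(n)
    opts = opts if opts is not None else FoldOptions()
    params = params if params is not None else load_parameters("default")
    m = matrices if matrices is not None else fill_matrices(seq, params, cs, opts)

    if opts.window is None and estimate_structure_count(n) > opts.max_structures:
        warnings.warn(
            f"combinatorial enumeration of a {n}-nt sequence may exceed the "
            f"safety cap of {opts.max_structures} structures",
            SafetyCapWarning,
            stacklevel=2,
        )

    threshold: int | None = None
    if opts.window is not None:
        if m.mfe_deci >= INF:
            return
        threshold = m.mfe_deci + round(opts.window * 10)

    root = root_state(m)
    if root.dg_sigma >= INF:
        return

    stream = _enumerate_low_memory if opts.low_memory else _enumerate_stack
    leaves = stream(root, m, seq, cs, opts, params, threshold)

    emitted = 0
    if opts.sort_output:
        out = sorted(leaves, key=lambda st: (round(st.energy * 10), st.to_dotbracket()))
        leaves = iter(out)
    for st in leaves:
        if opts.helix_filter is not None:
            from .filters import helix_filter_pass

            if not helix_filter_pass(st, opts.helix_filter):
                continue
        emitted += 1
        if emitted > opts.max_structures:
            raise EnumerationCapExceeded(
                f"more than {opts.max_structures} structures emitted"
            )
        yield st


def _enumerate_stack(root, m, seq, cs, opts, params, threshold):
    """Fig.-style stack refinement: all children of a state are created
    and pushed together, memory grows with stack width."""
    stack = [root]
    while stack:
        s = stack.pop()
        if s.is_leaf:
            yield _leaf_structure(s, m.n)
        else:
            stack.extend(refine_state(s, m, seq, cs, opts, params, threshold))


def _enumerate_low_memory(root, m, seq, cs, opts, params, threshold):
    """Depth-first variant holding a single branch per tree level: each
    frame stores one state plus the cursor of its child iteration, so
    retained states before the first emission are linear in length."""
    if root.is_leaf:
        yield _leaf_structure(root, m.n)
        return
    frames = [_iter_children(root, m, seq, cs, opts, params, threshold)]
    while frames:
        child = next(frames[-1], None)
        if child is None:
            frames.pop()
        elif child.is_leaf:
            yield _leaf_structure(child, m.n)
        else:
            frames.append(_iter_children(child, m, seq, cs, opts, params, threshold))


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_enumerate(
    seq: str,
    cs: ConstraintSet | None = None,
    min_hairpin: int = 3,
    max_n: int = 28,
) -> list[SecondaryStructure]:
    """All non-crossing pair sets over seq, with no energy model.

    Test oracle only: plain recursion over the rightmost position,
    hard constraints applied during generation and context-dependent /
    forced-pair presence constraints filtered post hoc. Guarded against
    combinatorial explosion.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n > max_n:
        raise ValidationError(f"brute force refused for n={n} > {max_n}")
    cs = cs if cs is not None else ConstraintSet.empty(n)
    h = min_hairpin
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(a: int, b: int) -> list[frozenset]:
        if a > b:
            return [frozenset()]
        key = (a, b)
        if key not in memo:
            out = list(rec(a, b - 1))
            for k in range(a, b - h):
                if cs.pair_allowed_hard(seq, k, b, min_hairpin=h):
                    for left in rec(a, k - 1):
                        for right in rec(k + 1, b - 1):
                            out.append(left | right | {(k, b)})
            memo[key] = out
        return memo[key]

    all_sets = rec(1, n)
    out = []
    for pairs in all_sets:
        st = SecondaryStructure(n=n, pairs=pairs)
        if structure_satisfies(st, seq, cs):
            out.append(st)
    return out
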