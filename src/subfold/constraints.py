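"""Hard and context-dependent experimental constraints.

Per-nucleotide codes (constraint-string alphabet):

* ``.`` — unconstrained;
* ``x`` — forced unpaired (hard single-strand constraint, e.g. an S1
  nuclease hit);
* ``(`` / ``)`` — a forced pair, matched like brackets; the two positions
  must pair with each other and nucleotides between them may only pair
  among themselves;
* ``m`` — chemically modified (probed): the nucleotide may pair, but never
  as a Watson-Crick pair flanked on both sides by Watson-Crick pairs.
  Pairing at a helix end, adjacent to a loop or bulge, in a GU pair, or
  adjacent to a GU pair remains admissible.

The probing rule is context dependent: whether a pair is admissible can
only be settled once its neighbor pairs are known, so the enumerator
re-applies :func:`allow_pair` whenever a pair proposal would complete the
Watson-Crick sandwich around an earlier probed pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConstraintConflictError, ValidationError
from .structure import DEFAULT_MIN_HAIRPIN, SecondaryStructure, can_pair, is_wc

CODE_NONE = "."
CODE_UNPAIRED = "x"
CODE_PAIRED = "p"   # set for both ends of a forced pair
CODE_PROBED = "m"


@dataclass
class ConstraintSet:
    """Per-position constraint codes plus forced pairs and global options."""

    n: int
    per_position: tuple[str, ...] = ()
    forced_pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    max_pair_span: int | None = None

    def __post_init__(self) -> None:
        if not self.per_position:
            self.per_position = (CODE_NONE,) * self.n
        self.forced_pairs = frozenset(
            (min(i, j), max(i, j)) for i, j in self.forced_pairs
        )
        self._partner = {}
        for i, j in self.forced_pairs:
            self._partner[i] = j
            self._partner[j] = i

    @classmethod
    def empty(cls, n: int) -> "ConstraintSet":
        return cls(n=n)

    # -- per-position queries (1-based) -------------------------------

    def code(self, i: int) -> str:
        return self.per_position[i - 1]

    def forced_unpaired(self, i: int) -> bool:
        return self.code(i) == CODE_UNPAIRED

    def forced_paired(self, i: int) -> bool:
        return self.code(i) == CODE_PAIRED

    def probed(self, i: int) -> bool:
        return self.code(i) == CODE_PROBED

    def forced_partner(self, i: int) -> int | None:
        return self._partner.get(i)

    def has_probing(self) -> bool:
        return CODE_PROBED in self.per_position

    # -- consistency ---------------------------------------------------

    def validate(self, min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> None:
        if len(self.per_position) != self.n:
            raise ValidationError("constraint codes do not match sequence length")
        for i, j in self.forced_pairs:
            for k in (i, j):
                if self.forced_unpaired(k):
                    raise ConstraintConflictError(
                        f"position {k} is both forced unpaired and in forced pair ({i},{j})"
                    )
            if j - i < min_hairpin + 1:
                raise ConstraintConflictError(
                    f"forced pair ({i},{j}) closes a hairpin shorter than {min_hairpin}"
                )
        ordered = sorted(self.forced_pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1:]:
                if i < k < j < l or i == k or j == l:
                    raise ConstraintConflictError(
                        f"forced pairs ({i},{j}) and ({k},{l}) conflict"
                    )
        if self.max_pair_span is not None and self.max_pair_span < min_hairpin + 1:
            raise ValidationError("max_pair_span below the minimum hairpin span")

    # -- hard pair admissibility --------------------------------------

    def pair_allowed_hard(
        self, seq: str, i: int, j: int, min_hairpin: int = DEFAULT_MIN_HAIRPIN
    ) -> bool:
        """Context-free part of pair admissibility: chemistry, distance,
        hard single-strand constraints, forced partners, span cap."""
        if j - i < min_hairpin + 1 or not can_pair(seq, i, j):
            return False
        if self.forced_unpaired(i) or self.forced_unpaired(j):
            return False
        if self.max_pair_span is not None and j - i > self.max_pair_span:
            return False
        pi, pj = self.forced_partner(i), self.forced_partner(j)
        if pi is not None and pi != j:
            return False
        if pj is not None and pj != i:
            return False
        return True

    def interval_unpairable(self, a: int, b: int) -> bool:
        """True if every position in [a, b] may stay unpaired."""
        return all(not self.forced_paired(k) for k in range(a, b + 1))


def parse_constraint_string(text: str, n: int) -> ConstraintSet:
    """Parse the dot/x/brackets/m constraint dialect (length must equal n)."""
    if len(text) != n:
        raise ValidationError(
            f"constraint string length {len(text)} != sequence length {n}"
        )
    codes = [CODE_NONE] * n
    pairs, stack = [], []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch == "x":
            codes[pos - 1] = CODE_UNPAIRED
        elif ch == "m":
            codes[pos - 1] = CODE_PROBED
        elif ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' in constraints at position {pos}")
            i = stack.pop()
            pairs.append((i, pos))
            codes[i - 1] = codes[pos - 1] = CODE_PAIRED
        else:
            raise ValidationError(f"illegal constraint character {ch!r} at position {pos}")
    if stack:
        raise ValidationError(f"unbalanced '(' in constraints at position {stack[-1]}")
    cs = ConstraintSet(n=n, per_position=tuple(codes), forced_pairs=frozenset(pairs))
    cs.validate()
    return cs


# ---------------------------------------------------------------------------
# context-dependent admissibility


def _partner_map(partial) -> dict[int, int]:
    if isinstance(partial, dict):
        return partial
    pairs = getattr(partial, "pairs", partial)
    pm: dict[int, int] = {}
    for i, j in pairs:
        pm[i], pm[j] = j, i
    return pm


def _probed_pair(cs: ConstraintSet, i: int, j: int) -> bool:
    return cs.probed(i) or cs.probed(j)


def _wc_neighbor(pm: dict[int, int], seq: str, i: int, j: int) -> bool:
    """Is (i, j) an existing Watson-Crick pair in the partner map?"""
    return i >= 1 and j <= len(seq) and pm.get(i) == j and is_wc(seq, i, j)


def allow_pair(i: int, j: int, partial, seq: str, cs: ConstraintSet) -> bool:
    """Admissibility of adding pair (i, j) to a partial structure.

    False when a hard constraint is violated, and false when the proposal
    would leave a probed nucleotide in a Watson-Crick pair flanked on both
    sides by Watson-Crick pairs — either (i, j) itself, or the already
    fixed neighbor pair (i-1, j+1) whose sandwich this proposal completes.
    Pure predicate; also usable post hoc on a complete structure.
    """
    if not cs.pair_allowed_hard(seq, i, j):
        return False
    if not cs.has_probing():
        return True
    pm = _partner_map(partial)
    if _probed_pair(cs, i, j) and is_wc(seq, i, j):
        if _wc_neighbor(pm, seq, i - 1, j + 1) and _wc_neighbor(pm, seq, i + 1, j - 1):
            return False
    # completing the sandwich around the outer neighbor pair
    if (
        pm.get(i - 1) == j + 1
        and _probed_pair(cs, i - 1, j + 1)
        and is_wc(seq, i - 1, j + 1)
        and is_wc(seq, i, j)
        and _wc_neighbor(pm, seq, i - 2, j + 2)
    ):
        return False
    return True


def structure_satisfies(structure: SecondaryStructure, seq: str, cs: ConstraintSet) -> bool:
    """Post-hoc check that a complete structure honors every constraint."""
    pm = structure.partner_map()
    for i in range(1, structure.n + 1):
        if cs.forced_unpaired(i) and i in pm:
            return False
        if cs.forced_paired(i) and i not in pm:
            return False
    for i, j in cs.forced_pairs:
        if pm.get(i) != j:
            return False
    for i, j in structure.pairs:
        if cs.max_pair_span is not None and j - i > cs.max_pair_span:
            return False
        if (
            cs.has_probing()
            and _probed_pair(cs, i, j)
            and is_wc(seq, i, j)
            and _wc_neighbor(pm, seq, i - 1, j + 1)
            and _wc_neighbor(pm, seq, i + 1, j - 1)
        ):
            return False
    return True
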