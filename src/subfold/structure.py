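"""Secondary structures as sets of base pairs, with dot-bracket rendering.

A secondary structure over an N-nucleotide sequence is a set of pairs
(i, j), 1 <= i < j <= N (1-based, closed intervals throughout the package),
such that no nucleotide is in two pairs, no two pairs cross (pseudoknot
free), and every hairpin loop holds at least ``min_hairpin`` unpaired
nucleotides (j - i >= min_hairpin + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: minimum number of unpaired nucleotides in a hairpin loop
DEFAULT_MIN_HAIRPIN = 3

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
ALLOWED_PAIRS = WC_PAIRS | WOBBLE_PAIRS

#: canonical ordering of the six pair types, used by the stack table
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = {p: k for k, p in enumerate(PAIR_TYPES)}


def normalize_sequence(seq: str) -> str:
    """Uppercase, DNA->RNA (T->U); reject characters outside ACGUN."""
    s = seq.upper().replace("T", "U")
    bad = sorted(set(s) - set("ACGUN"))
    if bad:
        raise ValidationError(f"illegal sequence characters: {''.join(bad)}")
    return s


def can_pair(seq: str, i: int, j: int) -> bool:
    """Chemical legality of pair (i, j) (1-based); N never pairs."""
    return (seq[i - 1], seq[j - 1]) in ALLOWED_PAIRS


def is_wc(seq: str, i: int, j: int) -> bool:
    """True for a Watson-Crick pair, false for GU/UG wobble."""
    return (seq[i - 1], seq[j - 1]) in WC_PAIRS


def pair_type(seq: str, i: int, j: int) -> str:
    return seq[i - 1] + seq[j - 1]


@dataclass
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of length n.

    ``energy`` is in kcal/mol and is None until evaluated (the open chain
    evaluates to exactly 0).
    """

    n: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    energy: float | None = None

    def __post_init__(self) -> None:
        self.pairs = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)

    # -- construction -------------------------------------------------

    @classmethod
    def from_dotbracket(cls, db: str, energy: float | None = None) -> "SecondaryStructure":
        pairs, stack = [], []
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValidationError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise ValidationError(f"illegal dot-bracket character {ch!r}")
        if stack:
            raise ValidationError(f"unbalanced '(' at position {stack[-1]}")
        return cls(n=len(db), pairs=frozenset(pairs), energy=energy)

    def to_dotbracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairs:
            out[i - 1], out[j - 1] = "(", ")"
        return "".join(out)

    # -- queries ------------------------------------------------------

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i], m[j] = j, i
        return m

    def validate(self, seq: str | None = None, min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> None:
        """Raise ValidationError naming the first violated rule."""
        seen: set[int] = set()
        for i, j in sorted(self.pairs):
            if not (1 <= i < j <= self.n):
                raise ValidationError(f"pair ({i},{j}) out of range 1..{self.n}")
            if i in seen or j in seen:
                raise ValidationError(f"nucleotide in two pairs at ({i},{j})")
            seen.update((i, j))
            if j - i < min_hairpin + 1:
                raise ValidationError(
                    f"hairpin loop of pair ({i},{j}) shorter than {min_hairpin}"
                )
            if seq is not None and not can_pair(seq, i, j):
                raise ValidationError(
                    f"pair ({i},{j}) = {pair_type(seq, i, j)} is not an allowed pair type"
                )
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1:]:
                if i < k < j < l:
                    raise ValidationError(f"pairs ({i},{j}) and ({k},{l}) cross")

    def __len__(self) -> int:
        return len(self.pairs)
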