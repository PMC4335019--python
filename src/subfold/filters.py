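"""Post-hoc helix filter and landscape metrics.

A helix is a run of consecutive base pairs; the run may extend across
single 1x1 internal-loop interruptions ("mismatches") up to a tolerance,
while bulges and anything larger than 1x1 always start a new helix. The
helix filter passes a completed structure when it holds at least a
required number of sufficiently long helices — the shape constraint used
for encapsidated viral RNA where crystallography fixes the number and
length of ordered helices.

Landscape metrics summarize an ensemble of structures relative to a
reference (by default the minimum-energy member): structure count, energy
span, and the maximum / mean base-pair distance, i.e. the size of the
symmetric difference of the pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError
from .structure import SecondaryStructure


@dataclass(frozen=True)
class HelixFilterSpec:
    """Pass criteria: >= min_helix_count helices of >= min_helix_length
    pairs, each counted with at most max_mismatches_per_helix 1x1
    interruptions."""

    min_helix_count: int
    min_helix_length: int
    max_mismatches_per_helix: int = 0

    def __post_init__(self) -> None:
        if self.min_helix_count < 0 or self.max_mismatches_per_helix < 0:
            raise ValidationError("helix filter fields must be >= 0")
        if self.min_helix_length < 1:
            raise ValidationError("min_helix_length must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "HelixFilterSpec":
        """Parse the CLI form COUNT:LEN:MISMATCH."""
        try:
            count, length, mm = (int(t) for t in text.split(":"))
        except ValueError as exc:
            raise ValidationError(f"bad helix filter spec {text!r}, want COUNT:LEN:MISMATCH") from exc
        return cls(count, length, mm)


@dataclass
class Helix:
    """A maximal run of pairs; mismatches counts its 1x1 interruptions."""

    pair_run: list[tuple[int, int]]
    mismatches: int

    @property
    def length(self) -> int:
        return len(self.pair_run)


def find_helices(structure: SecondaryStructure, max_mismatches: int = 0) -> list[Helix]:
    """Partition the pair set into maximal helices.

    Consecutive pairs (i, j), (i+1, j-1) stack; (i+2, j-2) with both
    skipped nucleotides unpaired is a 1x1 interruption and extends the
    helix while the accumulated interruptions stay within the tolerance.
    Every pair lands in exactly one helix.
    """
    pairs = sorted(structure.pairs)
    helices: list[Helix] = []
    used: set[tuple[int, int]] = set()
    pair_set = set(pairs)
    for start in pairs:
        if start in used:
            continue
        run, mismatches = [start], 0
        i, j = start
        while True:
            if (i + 1, j - 1) in pair_set:
                i, j = i + 1, j - 1
            elif (i + 2, j - 2) in pair_set and mismatches < max_mismatches:
                mismatches += 1
                i, j = i + 2, j - 2
            else:
                break
            run.append((i, j))
        used.update(run)
        helices.append(Helix(pair_run=run, mismatches=mismatches))
    return helices


def helix_filter_pass(structure: SecondaryStructure, spec: HelixFilterSpec) -> bool:
    """True iff enough sufficiently long helices exist under the spec."""
    helices = find_helices(structure, spec.max_mismatches_per_helix)
    long_enough = sum(1 for h in helices if h.length >= spec.min_helix_length)
    return long_enough >= spec.min_helix_count


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Pairs present in one structure and not the other (symmetric difference)."""
    if a.n != b.n:
        raise ValidationError(f"structure lengths differ: {a.n} != {b.n}")
    return len(a.pairs ^ b.pairs)


def nucleotide_difference(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Number of nucleotides paired differently in the two structures
    (secondary statistic; counts positions whose partner differs)."""
    if a.n != b.n:
        raise ValidationError(f"structure lengths differ: {a.n} != {b.n}")
    pa, pb = a.partner_map(), b.partner_map()
    return sum(1 for k in range(1, a.n + 1) if pa.get(k) != pb.get(k))


@dataclass
class LandscapeSummary:
    count: int
    min_energy: float
    max_energy: float
    energy_span: float
    max_distance: int
    mean_distance: float
    reference: SecondaryStructure


def landscape_summary(
    ensemble: Iterable[SecondaryStructure],
    reference: SecondaryStructure | None = None,
) -> LandscapeSummary:
    """Summarize an ensemble against a reference structure.

    The reference defaults to the minimum-energy member (the MFE structure
    of the run). Streams once; the ensemble must be non-empty and carry
    energies when the default reference is used.
    """
    members = list(ensemble)
    if not members:
        raise ValidationError("empty ensemble")
    if reference is None:
        if any(st.energy is None for st in members):
            raise ValidationError("default reference needs energies on every member")
        reference = min(members, key=lambda st: st.energy)
    dists = [base_pair_distance(st, reference) for st in members]
    energies = [st.energy for st in members if st.energy is not None]
    lo = min(energies) if energies else float("nan")
    hi = max(energies) if energies else float("nan")
    return LandscapeSummary(
        count=len(members),
        min_energy=lo,
        max_energy=hi,
        energy_span=hi - lo,
        max_distance=max(dists),
        mean_distance=sum(dists) / len(dists),
        reference=reference,
    )
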