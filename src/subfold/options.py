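"""Run options shared by the fill, enumeration and parallel stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import ValidationError
from .structure import DEFAULT_MIN_HAIRPIN

if TYPE_CHECKING:  # pragma: no cover
    from .filters import HelixFilterSpec


@dataclass
class FoldOptions:
    """Options controlling one folding / enumeration run.

    window
        Energy window above the MFE in kcal/mol. ``None`` means an
        infinite window (pure combinatorial enumeration).
    no_lonely_pairs
        Energy-independent pruning of branches in which a base pair can no
        longer acquire a stacked neighbor.
    no_multibranch
        Disable multibranch loops: no favorable multiloop term in the fill
        and no multiloop decomposition during backtracking, so every
        closed pair encloses at most one branch (the exterior loop may
        still hold many stems).
    low_memory
        Depth-first enumeration keeping a single branch per tree level, so
        retained state before the first emission is linear in sequence
        length.
    helix_filter
        Optional post-hoc filter on completed structures.
    sort_output
        Emit structures sorted by (energy, dot-bracket).
    min_hairpin
        Minimum unpaired nucleotides in a hairpin loop (default 3).
    max_structures
        Safety cap on emitted structures.
    """

    window: float | None = None
    no_lonely_pairs: bool = False
    no_multibranch: bool = False
    low_memory: bool = False
    helix_filter: "HelixFilterSpec | None" = None
    sort_output: bool = False
    min_hairpin: int = DEFAULT_MIN_HAIRPIN
    max_structures: int = 10 ** 8

    def __post_init__(self) -> None:
        if self.window is not None and self.window < 0:
            raise ValidationError("energy window must be >= 0 (or None for infinite)")
        if self.min_hairpin < 0:
            raise ValidationError("min_hairpin must be >= 0")
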