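"""Nearest-neighbor thermodynamic model and whole-structure evaluation.

Free energies are handled internally as integers in tenths of a kcal/mol
(decikcal) so that window comparisons during enumeration are exact; public
interfaces use kcal/mol floats.

The model is a compact Turner-style nearest-neighbor set:

* stacking free energies for every ordered combination of the six allowed
  pair types (AU, UA, CG, GC, GU, UG);
* hairpin / bulge / internal loop initiation tables to length 30, extended
  beyond with ``1.75 RT ln(L / 30)``;
* internal-loop asymmetry (Ninio) penalty, linear with a cap;
* an affine multiloop model ``a + b * branches + c * unpaired``;
* a terminal penalty for AU/UA/GU/UG helix-end pairs, charged once for
  every non-stack loop a pair borders;
* the exterior loop contributes zero beyond the per-branch terminal
  penalties.

Dangling ends and coaxial stacking are deliberately excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParameterError, ValidationError
from .structure import (
    DEFAULT_MIN_HAIRPIN,
    PAIR_INDEX,
    PAIR_TYPES,
    SecondaryStructure,
    pair_type,
)

#: sentinel for "no finite energy" in decikcal arithmetic
INF = 10 ** 9

MAX_TABULATED = 30


def _deci(x: float) -> int:
    return round(x * 10)


@dataclass
class EnergyParameters:
    """Parameter tables in integer decikcal (tenths of kcal/mol)."""

    stack_table: dict[tuple[str, str], int]
    hairpin_by_length: dict[int, int]      # 3..30
    bulge_by_length: dict[int, int]        # 1..30
    internal_by_length: dict[int, int]     # 2..30
    multiloop_closing: int                 # a
    multiloop_branch: int                  # b
    multiloop_unpaired: int                # c
    terminal_au_penalty: int
    ninio_m: int
    ninio_max: int
    loop_extrapolation_coefficient: float  # kcal/mol, multiplies ln(L/30)
    temperature: float                     # kelvin
    name: str = "default"

    # -- elementary terms (decikcal) ----------------------------------

    def _extend(self, table: dict[int, int], length: int) -> int:
        if length in table:
            return table[length]
        base = table[MAX_TABULATED]
        return base + _deci(
            self.loop_extrapolation_coefficient * math.log(length / MAX_TABULATED)
        )

    def hairpin_e(self, length: int) -> int:
        if length < DEFAULT_MIN_HAIRPIN:
            return INF
        return self._extend(self.hairpin_by_length, length)

    def bulge_e(self, length: int) -> int:
        return self._extend(self.bulge_by_length, length)

    def internal_e(self, n1: int, n2: int) -> int:
        init = self._extend(self.internal_by_length, n1 + n2)
        asym = min(self.ninio_m * abs(n1 - n2), self.ninio_max)
        return init + asym

    def stack_e(self, outer: str, inner: str) -> int:
        return self.stack_table[(outer, inner)]

    def au_e(self, ptype: str) -> int:
        """Terminal penalty for a helix-end pair of the given type."""
        return self.terminal_au_penalty if ptype != "CG" and ptype != "GC" else 0


def loop_energy(params: EnergyParameters, seq: str, i: int, j: int, p: int, q: int) -> int:
    """Energy (decikcal) of the two-pair loop closed by (i,j) with inner pair (p,q).

    Covers the stack (p = i+1, q = j-1), bulges (one side empty) and
    internal loops. Terminal penalties for both pairs are charged here for
    any loop with unpaired nucleotides; stacks carry none.
    """
    n1, n2 = p - i - 1, j - q - 1
    outer, inner = pair_type(seq, i, j), pair_type(seq, p, q)
    if n1 == 0 and n2 == 0:
        return params.stack_e(outer, inner)
    ends = params.au_e(outer) + params.au_e(inner)
    if n1 == 0 or n2 == 0:
        return params.bulge_e(n1 + n2) + ends
    return params.internal_e(n1, n2) + ends


# ---------------------------------------------------------------------------
# parameter loading


def _parse_blocks(text: str, source: str) -> dict[str, list[float]]:
    blocks: dict[str, list[float]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            blocks[current] = []
            continue
        if current is None:
            raise ParameterError(f"{source}: numbers before any [block] at line {lineno}")
        for tok in line.split():
            try:
                blocks[current].append(float(tok))
            except ValueError as exc:
                raise ParameterError(
                    f"{source}: bad number {tok!r} in [{current}] at line {lineno}"
                ) from exc
    return blocks


def load_parameters(source: str | Path = "default") -> EnergyParameters:
    """Load a parameter set from a file path or the builtin ``"default"``.

    The file dialect is plain-text blocks ``[stack]``, ``[hairpin]``,
    ``[bulge]``, ``[internal]``, ``[multiloop]``, ``[misc]`` holding
    whitespace-separated numbers in kcal/mol (see the shipped default for
    the exact layout).
    """
    if source == "default":
        text = resources.files("subfold").joinpath("params/default.par").read_text()
        name = "default"
    else:
        path = Path(source)
        if not path.is_file():
            raise IOError(f"parameter file not found: {path}")
        text = path.read_text()
        name = str(path)

    blocks = _parse_blocks(text, name)
    for block, want in (
        ("stack", 36), ("hairpin", 28), ("bulge", 30),
        ("internal", 29), ("multiloop", 3), ("misc", 5),
    ):
        if block not in blocks:
            raise ParameterError(f"{name}: missing [{block}] block")
        if len(blocks[block]) != want:
            raise ParameterError(
                f"{name}: [{block}] holds {len(blocks[block])} numbers, expected {want}"
            )

    stack = {}
    vals = blocks["stack"]
    for r, outer in enumerate(PAIR_TYPES):
        for c, inner in enumerate(PAIR_TYPES):
            stack[(outer, inner)] = _deci(vals[r * 6 + c])
    a, b, c = (_deci(v) for v in blocks["multiloop"])
    term_au, ninio_m, ninio_max, coef, temp = blocks["misc"]
    return EnergyParameters(
        stack_table=stack,
        hairpin_by_length={L: _deci(v) for L, v in zip(range(3, 31), blocks["hairpin"])},
        bulge_by_length={L: _deci(v) for L, v in zip(range(1, 31), blocks["bulge"])},
        internal_by_length={L: _deci(v) for L, v in zip(range(2, 31), blocks["internal"])},
        multiloop_closing=a,
        multiloop_branch=b,
        multiloop_unpaired=c,
        terminal_au_penalty=_deci(term_au),
        ninio_m=_deci(ninio_m),
        ninio_max=_deci(ninio_max),
        loop_extrapolation_coefficient=coef,
        temperature=temp,
        name=name,
    )


# ---------------------------------------------------------------------------
# structure evaluation


def _direct_children(pm: dict[int, int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal pairs directly enclosed in the open interval (lo, hi)."""
    children, k = [], lo
    while k <= hi:
        if k in pm and pm[k] > k:
            children.append((k, pm[k]))
            k = pm[k] + 1
        else:
            k += 1
    return children


def eval_structure_deci(
    seq: str,
    structure: SecondaryStructure,
    params: EnergyParameters,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> int:
    """Loop-decomposition free energy in decikcal; validates the structure."""
    if structure.n != len(seq):
        raise ValidationError(
            f"structure length {structure.n} != sequence length {len(seq)}"
        )
    structure.validate(seq, min_hairpin=min_hairpin)
    pm = structure.partner_map()
    total = sum(params.au_e(pair_type(seq, i, j))
                for i, j in _direct_children(pm, 1, structure.n))
    for i, j in structure.pairs:
        kids = _direct_children(pm, i + 1, j - 1)
        if not kids:
            total += params.hairpin_e(j - i - 1) + params.au_e(pair_type(seq, i, j))
        elif len(kids) == 1:
            p, q = kids[0]
            total += loop_energy(params, seq, i, j, p, q)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += (
                params.multiloop_closing
                + params.multiloop_branch * (len(kids) + 1)
                + params.multiloop_unpaired * unpaired
                + params.au_e(pair_type(seq, i, j))
                + sum(params.au_e(pair_type(seq, p, q)) for p, q in kids)
            )
    return total


def eval_structure(
    seq: str,
    structure: SecondaryStructure,
    params: EnergyParameters,
    min_hairpin: int = DEFAULT_MIN_HAIRPIN,
) -> float:
    """Free energy of a complete structure in kcal/mol (open chain = 0.0)."""
    return eval_structure_deci(seq, structure, params, min_hairpin) / 10.0
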