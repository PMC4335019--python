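"""Sequence/constraint readers, structure writers, manifests and fixtures.

Output dialect (subopt stream): a ``> name`` header line, the sequence,
then one line per structure — dot-bracket, a single space, energy with two
decimals. Constraint strings may sit on the line after the sequence in an
extended-FASTA, or in a standalone single-line file.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .constraints import ConstraintSet, parse_constraint_string
from .errors import ValidationError
from .structure import SecondaryStructure, normalize_sequence


@dataclass
class NamedSequence:
    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> NamedSequence:
    """First record of a FASTA file, uppercased and T->U normalized.

    Characters outside ACGUN are rejected; N positions never pair. A
    warning is emitted when the file holds more than one record.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    if len(records) > 1:
        warnings.warn(f"{path}: {len(records)} records, using the first", stacklevel=2)
    rec = records[0]
    seq = normalize_sequence(str(rec.seq))
    if not seq:
        raise ValidationError(f"{path}: empty sequence")
    return NamedSequence(name=rec.id or path.stem, seq=seq)


def read_constraints(path: str | Path, n: int) -> ConstraintSet:
    """Standalone constraint file: first non-empty, non-header line."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith((">", "#", ";")):
            return parse_constraint_string(line, n)
    raise ValidationError(f"{path}: no constraint line found")


def write_subopt(
    structures: Iterable[SecondaryStructure],
    destination: IO[str],
    name: str,
    seq: str,
    sort: bool = False,
) -> int:
    """Write the subopt stream; returns the number of structure lines.

    Sorted mode orders by energy then lexicographic dot-bracket.
    """
    destination.write(f"> {name}\n{seq}\n")
    if sort:
        structures = sorted(
            structures,
            key=lambda st: (round((st.energy or 0.0) * 10), st.to_dotbracket()),
        )
    count = 0
    for st in structures:
        destination.write(f"{st.to_dotbracket()} {st.energy or 0.0:.2f}\n")
        count += 1
    return count


def read_subopt(source: IO[str] | str | Path) -> tuple[str, str, list[SecondaryStructure]]:
    """Inverse of write_subopt: (name, sequence, structures)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2 or not lines[0].startswith(">"):
        raise ValidationError("not a subopt stream: missing header")
    name = lines[0][1:].strip()
    seq = normalize_sequence(lines[1].strip())
    structures = []
    for ln in lines[2:]:
        db, energy = ln.rsplit(" ", 1)
        structures.append(SecondaryStructure.from_dotbracket(db.strip(), float(energy)))
    return name, seq, structures


@dataclass
class RunManifest:
    """Key=value record that fully reconstructs a run configuration."""

    name: str
    length: int
    parameter_set: str
    window: float | None
    no_lonely_pairs: bool
    no_multibranch: bool
    low_memory: bool
    helix_filter: str | None
    constraints: str | None
    n_workers: int
    share_threshold: int | None
    structure_count: int
    mfe: float | None
    seed: int | None = None

    def to_text(self) -> str:
        return "".join(f"{k}={v}\n" for k, v in vars(self).items())


# ---------------------------------------------------------------------------
# synthetic fixtures


@dataclass
class Fixture:
    seq: str
    constraints: ConstraintSet
    expected: dict

    def __iter__(self) -> Iterator:
        return iter((self.seq, self.constraints, self.expected))


#: designed hairpin: pairs (1,16)..(6,11) instantiate every probing context
_PLANTED_SEQ = "GAGUCAAAAAUGGCUC"
_PLANTED_PAIRS = frozenset({(1, 16), (2, 15), (3, 14), (4, 13), (5, 12), (6, 11)})


def generate_fixture(kind: str, n: int = 16, seed: int = 0) -> Fixture:
    """Deterministic synthetic fixtures for testing.

    ``random_seq`` draws a uniform ACGU sequence of length n under the
    seed. ``planted_probing`` returns a designed hairpin whose full helix
    instantiates every context case of the probing rule at known
    positions — helix end, loop-adjacent, GU pair, GU-adjacent, and the
    one inadmissible case, a Watson-Crick pair sandwiched between two
    Watson-Crick pairs — with the expected admissibility recorded.
    """
    if kind == "random_seq":
        if n > 28:
            raise ValidationError("fixtures stay within brute-force-verifiable sizes")
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        return Fixture(seq=seq, constraints=ConstraintSet.empty(n), expected={})
    if kind == "planted_probing":
        seq = _PLANTED_SEQ
        # admissibility of keeping the full planted helix when the given
        # position is marked probed ('m')
        expected = {
            "helix_pairs": _PLANTED_PAIRS,
            "admissible_probed": {
                1: True,    # helix end (no outer neighbor possible)
                6: True,    # WC pair adjacent to the hairpin loop
                4: True,    # in a GU pair
                5: True,    # WC pair adjacent to a GU pair
                2: False,   # WC pair between two WC pairs
                15: False,  # partner of position 2
            },
        }
        return Fixture(seq=seq, constraints=ConstraintSet.empty(len(seq)), expected=expected)
    raise ValidationError(f"unknown fixture kind {kind!r}")
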