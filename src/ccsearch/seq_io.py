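"""FASTA I/O, the BLOSUM62 scoring matrix, and the 10-group reduced alphabet.

The reduced amino-acid alphabet partitions the 20 standard residues into ten
groups of biochemically interchangeable letters derived from BLOSUM62:

    (A) (K,R) (E,D,N,Q) (C) (G) (H) (I,L,V,M) (F,Y,W) (P) (S,T)

Each group is written with a single symbol (its alphabetically first member),
so similar residues become indistinguishable during seed matching, which
buys sensitivity at no cost in the fine search (always run on the original
letters).  The unknown residue ``X`` is kept as its own symbol and is
excluded from keys and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: the ten-group partition of the 20 standard amino acids
GROUPS: tuple[str, ...] = ("A", "KR", "EDNQ", "C", "G", "H", "ILVM", "FYW", "P", "ST")


class FastaParseError(ValueError):
    """Malformed FASTA input (position information in the message)."""


@dataclass(frozen=True)
class ProteinSequence:
    """One identified amino-acid sequence from a FASTA record."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


class ScoringMatrix:
    """BLOSUM62 substitution scores with integer letter-pair lookup.

    Wraps Biopython's vendored BLOSUM62 table (standard NCBI layout, which
    also carries X/B/Z rows) and exposes plain-int scores.
    """

    def __init__(self, name: str = "BLOSUM62") -> None:
        self.name = name
        self._array = substitution_matrices.load(name)
        self.alphabet = str(self._array.alphabet)

    def score(self, a: str, b: str) -> int:
        return int(self._array[a, b])

    def self_score(self, residues: str) -> int:
        """Score of aligning ``residues`` against itself, no gaps."""
        return sum(int(self._array[c, c]) for c in residues)

    @property
    def biopython(self):
        """The underlying ``Bio.Align.substitution_matrices.Array``."""
        return self._array


def _build_reduction(groups: tuple[str, ...], matrix: ScoringMatrix):
    symbol_of: dict[str, str] = {}
    symbols: list[str] = []
    max_diag: dict[str, int] = {}
    for members in groups:
        sym = min(members)
        symbols.append(sym)
        diag = max(matrix.score(a, a) for a in members)
        for a in members:
            symbol_of[a] = sym
            max_diag[a] = diag
    # X: singleton out-of-group symbol, never key/seed material
    symbol_of["X"] = "X"
    max_diag["X"] = -1
    return symbol_of, tuple(symbols), max_diag


@dataclass(frozen=True)
class ReducedAlphabet:
    """The 10-group reduction plus per-residue grouped-max diagonal scores.

    ``group_max_diag[r]`` is the largest BLOSUM62 self-score among the
    members of r's group; it is the per-residue contribution used when
    scoring candidate keys.
    """

    groups: tuple[str, ...] = GROUPS
    matrix: ScoringMatrix = field(default_factory=ScoringMatrix)

    def __post_init__(self) -> None:
        symbol_of, symbols, max_diag = _build_reduction(self.groups, self.matrix)
        object.__setattr__(self, "_symbol_of", symbol_of)
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "group_max_diag", max_diag)

    def reduce_sequence(self, residues: str) -> str:
        """Map every residue to its group symbol (length preserving).

        Raises ``ValueError`` naming the 1-based position of the first
        character outside the 20-letter alphabet (plus X).
        """
        out = []
        table: dict[str, str] = self._symbol_of  # type: ignore[attr-defined]
        for i, c in enumerate(residues):
            sym = table.get(c)
            if sym is None:
                raise ValueError(f"non-amino-acid character {c!r} at position {i + 1}")
            out.append(sym)
        return "".join(out)

    def symbol(self, residue: str) -> str:
        return self._symbol_of[residue]  # type: ignore[attr-defined]


#: module-level default instances (the matrix is a static table)
BLOSUM62 = ScoringMatrix()
REDUCED = ReducedAlphabet(matrix=BLOSUM62)


def reduce_sequence(residues: str) -> str:
    """Reduce ``residues`` with the default 10-group alphabet."""
    return REDUCED.reduce_sequence(residues)


def _validate_residues(seq_id: str, residues: str) -> None:
    allowed = set(STANDARD_RESIDUES) | {"X"}
    for i, c in enumerate(residues):
        if c not in allowed:
            raise FastaParseError(
                f"record {seq_id!r}: unsupported residue {c!r} at position {i + 1} "
                "(standard 20-letter alphabet plus X expected)"
            )


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file into an ordered list of records.

    Residues are upper-cased; blank lines are tolerated; a record with an
    empty sequence, a duplicate id, or non-amino-acid letters is rejected.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = None
        for line in handle:
            if line.strip():
                first = line
                break
        if first is None:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
        if not first.startswith(">"):
            raise FastaParseError(f"{path}: sequence line before any '>' header: {first.strip()!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        _validate_residues(rec.id, residues)
        records.append(ProteinSequence(id=rec.id, residues=residues, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write records to ``path`` wrapped at 60 residues per line."""
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for n, i in enumerate(ids) if i in ids[:n])
        raise ValueError(f"duplicate sequence id {dup!r}")
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)
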