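"""Synthetic protein families with controlled local redundancy.

Real protein databases are locally redundant: many sequences share long,
nearly identical blocks (domains, paralogs, strain variants) embedded in
otherwise unrelated context.  The generator emulates exactly that
structure and nothing else: each family owns a shared block, the family
founder carries it verbatim, and the other members carry copies mutated by
point substitutions and short indels at stated per-residue rates, embedded
at a chosen position (prefix / middle / suffix / whole) inside uniform
random background residues.  Queries are (optionally mutated) copies of
database sequences with the source recorded, so recall is checkable
against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ccsearch.seq_io import STANDARD_RESIDUES, ProteinSequence

PLACEMENTS = ("prefix", "middle", "suffix", "whole")


@dataclass(frozen=True)
class FamilySpec:
    """Shape and noise of one generated database."""

    n_families: int = 10
    members_per_family: int = 5
    rep_length: int = 120
    block_length: int = 45
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    placement: str = "middle"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")
        if self.block_length < 15:
            raise ValueError("block_length must be >= 15 (minimum removable span)")
        if self.placement != "whole" and self.rep_length < self.block_length + 20:
            raise ValueError("rep_length too short to embed the block with context")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")


@dataclass
class GroundTruth:
    """What the generator planted: family labels and query homologs."""

    family_of: dict[str, int] = field(default_factory=dict)
    homolog_of: dict[str, str] = field(default_factory=dict)

    def expected_redundant(self, id_a: str, id_b: str) -> bool:
        """True when two distinct database sequences share a planted block."""
        if id_a == id_b:
            return False
        fa, fb = self.family_of.get(id_a), self.family_of.get(id_b)
        return fa is not None and fa == fb


def _random_residues(rng: np.random.Generator, n: int) -> str:
    letters = np.array(list(STANDARD_RESIDUES))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


def _mutate(rng: np.random.Generator, residues: str, sub_rate: float, indel_rate: float) -> str:
    """Point substitutions and single-residue indels at per-position rates."""
    out: list[str] = []
    alphabet = STANDARD_RESIDUES
    for c in residues:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(alphabet[rng.integers(0, 20)])  # insertion before c
        if rng.random() < sub_rate:
            choices = alphabet.replace(c, "")
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(c)
    return "".join(out) or residues[:1]


def make_database(spec: FamilySpec) -> tuple[list[ProteinSequence], GroundTruth]:
    """Generate families of block-sharing sequences plus their ground truth.

    The founder of family f (id ``f<f>m0``) carries the pristine block;
    members carry mutated copies.  Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sequences: list[ProteinSequence] = []
    truth = GroundTruth()
    for f in range(spec.n_families):
        block = _random_residues(rng, spec.block_length)
        for m in range(spec.members_per_family):
            member_block = (
                block
                if m == 0
                else _mutate(rng, block, spec.substitution_rate, spec.indel_rate)
            )
            if spec.placement == "whole":
                residues = member_block
            else:
                context = spec.rep_length - spec.block_length
                if spec.placement == "prefix":
                    left = 0
                elif spec.placement == "suffix":
                    left = context
                else:
                    left = int(rng.integers(10, context - 9))
                residues = (
                    _random_residues(rng, left)
                    + member_block
                    + _random_residues(rng, context - left)
                )
            seq_id = f"f{f}m{m}"
            sequences.append(
                ProteinSequence(id=seq_id, residues=residues, description=f"{seq_id} family={f}")
            )
            truth.family_of[seq_id] = f
    return sequences, truth


def make_queries(
    database: Sequence[ProteinSequence],
    truth: GroundTruth,
    n_queries: int,
    mutation_rate: float = 0.0,
    rng_seed: int = 0,
    indel_rate: float = 0.0,
) -> list[ProteinSequence]:
    """Draw queries as mutated copies of database sequences, homolog recorded.

    Sampling is without replacement; at rate 0 the queries are verbatim
    copies.  The planted homolog of query ``q<i>`` is written into
    ``truth.homolog_of``.
    """
    if n_queries > len(database):
        raise ValueError(
            f"cannot draw {n_queries} queries without replacement from "
            f"{len(database)} sequences"
        )
    rng = np.random.default_rng(rng_seed)
    picks = rng.choice(len(database), size=n_queries, replace=False)
    queries: list[ProteinSequence] = []
    for i, src_idx in enumerate(picks):
        source = database[int(src_idx)]
        residues = (
            source.residues
            if mutation_rate == 0 and indel_rate == 0
            else _mutate(rng, source.residues, mutation_rate, indel_rate)
        )
        qid = f"q{i}"
        queries.append(
            ProteinSequence(id=qid, residues=residues, description=f"{qid} source={source.id}")
        )
        truth.homolog_of[qid] = source.id
    return queries


def write_truth_tsv(truth: GroundTruth, path) -> None:
    """Two-column records: F <id> <family> and H <query> <homolog>."""
    with open(path, "w") as fh:
        for seq_id, fam in truth.family_of.items():
            fh.write(f"F\t{seq_id}\t{fam}\n")
        for qid, hid in truth.homolog_of.items():
            fh.write(f"H\t{qid}\t{hid}\n")


def read_truth_tsv(path) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        for line in fh:
            kind, a, b = line.rstrip("\n").split("\t")
            if kind == "F":
                truth.family_of[a] = int(b)
            elif kind == "H":
                truth.homolog_of[a] = b
            else:
                raise ValueError(f"unknown truth record {kind!r}")
    return truth
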