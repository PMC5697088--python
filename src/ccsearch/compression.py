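"""Lossless redundancy removal with key-entry maps and difference scripts.

A collection is compressed in input order.  Every overlapping 5-residue
word ("key") of the already-retained segment pool is indexed in a
key-entry pair map; when a new sequence reaches a position whose 5-mer
matches an indexed key, the two downstream subsequences (key start to
sequence end on both sides) are globally aligned and the longest aligned
prefix whose identity clears the similarity threshold is removed from the
new sequence.  The removed span is replaced by a difference script — the
representative's coordinates plus replace/insert/delete operations with
residue-distance offsets — so decompression reproduces the original
residues exactly.  Whatever survives of a sequence (its residual) joins
the segment pool and is indexed for later sequences; earlier sequences
therefore act as representatives for later ones.

Offsets count residues in the *representative* span: an operation's digit
is the distance from the previous operation's position (or from the span
start for the first operation) to the affected representative residue; for
an insertion, to the representative residue before which the new residue
is placed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from ccsearch.alignment_engine import GAP, needleman_wunsch, nw_similarity
from ccsearch.seq_io import ProteinSequence, read_fasta, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_KEY_LEN = 5
DEFAULT_SIMILARITY_THRESHOLD = 0.80
#: spans shorter than this are never removed (3 x key length); prevents
#: fragmenting sequences into confetti over chance 5-mer matches
MIN_REMOVABLE_SPAN = 15

SLOTS = ("prefix", "middle", "suffix", "whole")


class CorruptionError(RuntimeError):
    """A script or provenance record is inconsistent with its pool."""


@dataclass
class Entry:
    """One key occurrence: pool-segment index, 1-based start, chain link."""

    seq_index: int
    start_pos: int
    next: Optional["Entry"] = None


class KeyEntryMap:
    """Mapping from words to linked occurrence chains.

    ``key_len=None`` admits variable-length keys (the clustering stage);
    otherwise every key must have exactly ``key_len`` residues.
    """

    def __init__(self, key_len: Optional[int] = DEFAULT_KEY_LEN) -> None:
        if key_len is not None and key_len < 1:
            raise ValueError("key_len must be >= 1")
        self.key_len = key_len
        self._heads: dict[str, Entry] = {}
        self._tails: dict[str, Entry] = {}
        self.n_entries = 0

    def add(self, key: str, seq_index: int, start_pos: int) -> None:
        if self.key_len is not None and len(key) != self.key_len:
            raise ValueError(f"key {key!r} is not length {self.key_len}")
        entry = Entry(seq_index, start_pos)
        tail = self._tails.get(key)
        if tail is None:
            self._heads[key] = entry
        else:
            tail.next = entry
        self._tails[key] = entry
        self.n_entries += 1

    def occurrences(self, key: str) -> Iterator[Entry]:
        entry = self._heads.get(key)
        while entry is not None:
            yield entry
            entry = entry.next

    def __contains__(self, key: str) -> bool:
        return key in self._heads

    def keys(self):
        return self._heads.keys()

    def add_sequence(self, seq_index: int, residues: str) -> None:
        """Index every overlapping key-length window of one segment."""
        k = self.key_len
        if len(residues) < k:
            logger.debug("segment %d shorter than key length, no entries", seq_index)
            return
        for p in range(len(residues) - k + 1):
            self.add(residues[p : p + k], seq_index, p + 1)


def build_key_entry_map(
    sequences: Sequence[ProteinSequence], key_len: int = DEFAULT_KEY_LEN
) -> KeyEntryMap:
    """Index all overlapping ``key_len`` windows of every sequence."""
    kmap = KeyEntryMap(key_len)
    for idx, seq in enumerate(sequences):
        kmap.add_sequence(idx, seq.residues)
    return kmap


# ---------------------------------------------------------------------------
# difference scripts

_OP_RE = re.compile(r"^([rid])(\d+)([A-Z]?)$")


@dataclass(frozen=True)
class EditOp:
    kind: str  # r / i / d
    offset: int
    residue: str = ""

    def __post_init__(self) -> None:
        if self.kind not in "rid":
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        if (self.kind in "ri") != bool(self.residue):
            raise ValueError("residue present iff kind is r or i")

    def __str__(self) -> str:
        return f"{self.kind}{self.offset}{self.residue}"


def parse_ops(text: str) -> list[EditOp]:
    """Parse an op list like ``"r6L, r8A, r3V, i5D"``."""
    text = text.strip()
    if not text or text == "-":
        return []
    ops = []
    for token in text.split(","):
        m = _OP_RE.match(token.strip())
        if m is None:
            raise ValueError(f"malformed edit operation {token.strip()!r}")
        kind, offset, residue = m.group(1), int(m.group(2)), m.group(3)
        ops.append(EditOp(kind, offset, residue))
    return ops


def format_ops(ops: Sequence[EditOp]) -> str:
    return ",".join(str(op) for op in ops) if ops else "-"


@dataclass(frozen=True)
class DiffScript:
    """Locates a removed span on its representative and lists its edits."""

    rep_id: str
    start: int  # 1-based inclusive, representative coordinates
    end: int
    ops: tuple[EditOp, ...]
    owner_id: str
    owner_slot: str = "middle"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("need 1 <= start <= end")
        if self.owner_slot not in SLOTS:
            raise ValueError(f"unknown slot {self.owner_slot!r}")


def _ops_from_alignment(row_rep: str, row_removed: str) -> tuple[EditOp, ...]:
    """Derive edit ops from two gapped alignment rows (rep, removed)."""
    ops: list[EditOp] = []
    since_last = 0  # rep residues since the previous op's position
    for a, b in zip(row_rep, row_removed):
        if a == GAP:
            ops.append(EditOp("i", since_last + 1, b))
            since_last = 0
        elif b == GAP:
            ops.append(EditOp("d", since_last + 1))
            since_last = 0
        elif a == b:
            since_last += 1
        else:
            ops.append(EditOp("r", since_last + 1, b))
            since_last = 0
    return tuple(ops)


def apply_ops(rep_span: str, ops: Sequence[EditOp]) -> str:
    """Apply edit ops to a representative span, reproducing the removed span."""
    out: list[str] = []
    pos = 0  # rep residues consumed
    for op in ops:
        if op.kind == "i":
            need = op.offset - 1
        else:
            need = op.offset
        if pos + need > len(rep_span):
            raise CorruptionError(
                f"op {op} runs past the end of a {len(rep_span)}-residue span"
            )
        out.append(rep_span[pos : pos + op.offset - 1])
        if op.kind == "r":
            out.append(op.residue)
            pos += op.offset
        elif op.kind == "d":
            pos += op.offset
        else:  # insert before the offset-th residue
            out.append(op.residue)
            pos += op.offset - 1
    out.append(rep_span[pos:])
    return "".join(out)


def encode_diff_script(
    rep_span: str,
    removed_span: str,
    rep_id: str,
    start: int,
    owner_id: str,
    owner_slot: str = "middle",
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> DiffScript:
    """Encode the differences of ``removed_span`` against ``rep_span``.

    Refuses to encode spans whose global-alignment identity does not clear
    the admission threshold (redundancy removal only applies above it).
    """
    sim = nw_similarity(rep_span, removed_span)
    if not (sim > similarity_threshold or sim == 1.0):
        raise ValueError(
            f"span similarity {sim:.3f} does not clear threshold {similarity_threshold:.2f}"
        )
    if rep_span == removed_span:
        ops: tuple[EditOp, ...] = ()
    else:
        aln = needleman_wunsch(rep_span, removed_span)
        ops = _ops_from_alignment(aln.aligned_query, aln.aligned_subject)
    return DiffScript(
        rep_id=rep_id,
        start=start,
        end=start + len(rep_span) - 1,
        ops=ops,
        owner_id=owner_id,
        owner_slot=owner_slot,
    )


def decode_diff_script(rep_span: str, script: DiffScript) -> str:
    """Reproduce the removed span from its representative span."""
    if script.end - script.start + 1 != len(rep_span):
        raise CorruptionError(
            f"script span {script.start}-{script.end} does not match a "
            f"{len(rep_span)}-residue representative span"
        )
    return apply_ops(rep_span, script.ops)


# ---------------------------------------------------------------------------
# whole-collection compression

#: provenance items: ("L", n_residues from own residual) or ("S", script idx)
ProvItem = tuple[str, int]


@dataclass
class Provenance:
    owner_id: str
    description: str
    parts: list[ProvItem] = field(default_factory=list)


@dataclass(frozen=True)
class CompressionParams:
    key_len: int = DEFAULT_KEY_LEN
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    min_removable_span: int = MIN_REMOVABLE_SPAN

    def __post_init__(self) -> None:
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.key_len < 1 or self.min_removable_span < self.key_len:
            raise ValueError("invalid key/span lengths")


@dataclass
class CompressedDB:
    """Non-redundant segment pool + scripts + per-sequence assembly plans."""

    segments: list[ProteinSequence]
    scripts: list[DiffScript]
    provenance: list[Provenance]
    params: CompressionParams

    def __post_init__(self) -> None:
        self._index = {seg.id: i for i, seg in enumerate(self.segments)}

    def segment_by_id(self, seg_id: str) -> ProteinSequence:
        try:
            return self.segments[self._index[seg_id]]
        except KeyError:
            raise CorruptionError(f"dangling reference to pool segment {seg_id!r}") from None

    def segment_index(self, seg_id: str) -> int:
        return self._index[seg_id]

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.segments)


def _slot(start: int, end: int, total: int) -> str:
    at_front, at_back = start == 0, end == total
    if at_front and at_back:
        return "whole"
    if at_front:
        return "prefix"
    if at_back:
        return "suffix"
    return "middle"


def _qualifying_prefix(
    rep_span: str, cand_span: str, params: CompressionParams
) -> Optional[tuple[int, int, tuple[EditOp, ...]]]:
    """Longest aligned prefix of (rep, cand) whose identity clears the bar.

    Aligns the full spans globally, walks the columns, and keeps the last
    match column at which prefix identity clears the threshold and the
    candidate prefix is long enough to remove.  Returns (rep residues used,
    cand residues used, edit ops) or None.
    """
    thr = params.similarity_threshold
    aln = needleman_wunsch(rep_span, cand_span)
    row_rep, row_cand = aln.aligned_query, aln.aligned_subject
    matches = rep_used = cand_used = 0
    best: Optional[tuple[int, int, int]] = None
    for col, (a, b) in enumerate(zip(row_rep, row_cand), start=1):
        if a != GAP:
            rep_used += 1
        if b != GAP:
            cand_used += 1
        if a == b and a != GAP:
            matches += 1
            sim = matches / col
            if cand_used >= params.min_removable_span and (sim > thr or sim == 1.0):
                best = (col, rep_used, cand_used)
    if best is None:
        return None
    col, rep_used, cand_used = best
    ops = _ops_from_alignment(row_rep[:col], row_cand[:col])
    return rep_used, cand_used, ops


def compress_collection(
    sequences: Sequence[ProteinSequence], params: CompressionParams = CompressionParams()
) -> CompressedDB:
    """Compress a collection in input order; earlier sequences represent later.

    The pool is seeded empty; each sequence is scanned left to right against
    the keys of already-retained segments, redundant spans are replaced by
    difference scripts, and the sequence's residual (possibly the whole
    sequence, possibly nothing) is appended to the pool and indexed.
    """
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input collection")
    kmap = KeyEntryMap(params.key_len)
    segments: list[ProteinSequence] = []
    scripts: list[DiffScript] = []
    provenance: list[Provenance] = []
    k = params.key_len

    for seq in sequences:
        res = seq.residues
        prov = Provenance(owner_id=seq.id, description=seq.description)
        residual_chunks: list[str] = []
        p = 0  # 0-based scan position
        lit_begin = 0
        while p + k <= len(res):
            key = res[p : p + k]
            found = None
            if key in kmap:
                for entry in kmap.occurrences(key):
                    rep_seg = segments[entry.seq_index]
                    rep_span = rep_seg.residues[entry.start_pos - 1 :]
                    hit = _qualifying_prefix(rep_span, res[p:], params)
                    if hit is not None:
                        found = (entry, hit)
                        break
            if found is None:
                p += 1
                continue
            entry, (rep_used, cand_used, ops) = found
            if p > lit_begin:
                chunk = res[lit_begin:p]
                residual_chunks.append(chunk)
                prov.parts.append(("L", len(chunk)))
            rep_seg = segments[entry.seq_index]
            script = DiffScript(
                rep_id=rep_seg.id,
                start=entry.start_pos,
                end=entry.start_pos + rep_used - 1,
                ops=ops,
                owner_id=seq.id,
                owner_slot=_slot(p, p + cand_used, len(res)),
            )
            prov.parts.append(("S", len(scripts)))
            scripts.append(script)
            p += cand_used
            lit_begin = p
        if lit_begin < len(res):
            chunk = res[lit_begin:]
            residual_chunks.append(chunk)
            prov.parts.append(("L", len(chunk)))
        residual = "".join(residual_chunks)
        if residual:
            seg = ProteinSequence(id=seq.id, residues=residual, description=seq.description)
            kmap.add_sequence(len(segments), residual)
            segments.append(seg)
        provenance.append(prov)
    db = CompressedDB(segments=segments, scripts=scripts, provenance=provenance, params=params)
    logger.info(
        "compressed %d sequences (%d residues) to %d segments (%d residues), %d scripts",
        len(sequences),
        sum(len(s) for s in sequences),
        len(segments),
        db.total_residues,
        len(scripts),
    )
    return db


def decompress_one(db: CompressedDB, prov: Provenance) -> ProteinSequence:
    """Reassemble one original sequence from its provenance plan."""
    pieces: list[str] = []
    cursor = 0
    residual = ""
    if prov.owner_id in db._index:
        residual = db.segment_by_id(prov.owner_id).residues
    for kind, value in prov.parts:
        if kind == "L":
            if cursor + value > len(residual):
                raise CorruptionError(
                    f"{prov.owner_id}: literal part overruns its residual segment"
                )
            pieces.append(residual[cursor : cursor + value])
            cursor += value
        elif kind == "S":
            try:
                script = db.scripts[value]
            except IndexError:
                raise CorruptionError(f"{prov.owner_id}: dangling script #{value}") from None
            rep = db.segment_by_id(script.rep_id)
            rep_span = rep.residues[script.start - 1 : script.end]
            pieces.append(decode_diff_script(rep_span, script))
        else:  # pragma: no cover - guarded at parse time
            raise CorruptionError(f"unknown provenance item kind {kind!r}")
    if cursor != len(residual):
        raise CorruptionError(f"{prov.owner_id}: residual segment not fully consumed")
    return ProteinSequence(id=prov.owner_id, residues="".join(pieces), description=prov.description)


def decompress(db: CompressedDB) -> list[ProteinSequence]:
    """Reconstruct the original collection, ids, order and residues intact."""
    return [decompress_one(db, prov) for prov in db.provenance]


# ---------------------------------------------------------------------------
# sidecar persistence (pool FASTA + text sidecar)

SIDECAR_MAGIC = "# ccsearch-compressed v1"


def save_compressed(db: CompressedDB, pool_path: str | Path, sidecar_path: str | Path) -> None:
    """Write the pool as FASTA and scripts/provenance as a text sidecar.

    Sidecar grammar (tab-separated, one record per line):

    - ``S <idx> <owner_id> <slot> <rep_id>,<start>,<end> <op[,op...]|->``
    - ``P <owner_id> <item[;item...]|->`` with items ``L:<len>`` / ``S:<idx>``
    """
    write_fasta(db.segments, pool_path)
    with open(sidecar_path, "w") as fh:
        fh.write(
            f"{SIDECAR_MAGIC}\tkey_len={db.params.key_len}"
            f"\tsimilarity_threshold={db.params.similarity_threshold!r}"
            f"\tmin_removable_span={db.params.min_removable_span}\n"
        )
        for i, s in enumerate(db.scripts):
            fh.write(
                f"S\t{i}\t{s.owner_id}\t{s.owner_slot}\t"
                f"{s.rep_id},{s.start},{s.end}\t{format_ops(s.ops)}\n"
            )
        for prov in db.provenance:
            items = ";".join(f"{k}:{v}" for k, v in prov.parts) or "-"
            fh.write(f"P\t{prov.owner_id}\t{items}\n")


def load_compressed(pool_path: str | Path, sidecar_path: str | Path) -> CompressedDB:
    segments = read_fasta(pool_path)
    scripts: dict[int, DiffScript] = {}
    provenance: list[Provenance] = []
    with open(sidecar_path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(SIDECAR_MAGIC):
            raise CorruptionError(f"{sidecar_path}: not a ccsearch sidecar")
        kv = dict(item.split("=", 1) for item in header.split("\t")[1:])
        params = CompressionParams(
            key_len=int(kv["key_len"]),
            similarity_threshold=float(kv["similarity_threshold"]),
            min_removable_span=int(kv["min_removable_span"]),
        )
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "S":
                idx = int(fields[1])
                rep_id, start, end = fields[4].rsplit(",", 2)
                scripts[idx] = DiffScript(
                    rep_id=rep_id,
                    start=int(start),
                    end=int(end),
                    ops=tuple(parse_ops(fields[5])),
                    owner_id=fields[2],
                    owner_slot=fields[3],
                )
            elif fields[0] == "P":
                parts: list[ProvItem] = []
                if fields[2] != "-":
                    for item in fields[2].split(";"):
                        kind, value = item.split(":")
                        parts.append((kind, int(value)))
                provenance.append(Provenance(owner_id=fields[1], description="", parts=parts))
            else:
                raise CorruptionError(f"{sidecar_path}: unknown record type {fields[0]!r}")
    script_list = [scripts[i] for i in range(len(scripts))]
    db = CompressedDB(segments=segments, scripts=script_list, provenance=provenance, params=params)
    # reattach descriptions carried by the pool FASTA where available
    for prov in db.provenance:
        if prov.owner_id in db._index:
            desc = db.segment_by_id(prov.owner_id).description
            prov.description = desc
    return db
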