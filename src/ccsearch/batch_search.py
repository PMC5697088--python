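"""Online phase: query compression, seed matching, hits, execution DB, fine search.

Queries are compressed exactly like the database (threshold T_t), their
compressed segments are scanned into reduced-alphabet 10-mer seeds (step 1),
and every query seed is compared against the cluster representatives of the
offline index.  An identical representative triggers a fragment-identity
check (threshold T_s on the recovered original residues) and, on success,
extension of every cluster member.  A non-identical representative at
Hamming distance d_qr can still hide a qualifying member because members may
sit up to distance 1 from their representative (cluster threshold T_c =
90% on 10 residues); the triangle inequality

    d(S_q, S_m) >= d(S_q, S_r) - d(S_r, S_m)

bounds the closest possible member at d_qr - 1, so clusters with
d_qr - 1 <= max_member_dist are examined member by member and no member
within the fragment radius is ever pruned.

Members are anchor-extended (ungapped x-drop, then gapped Smith-Waterman
over the segment pair) into hits; hit segments recruit, via the compression
scripts, every original sequence that depends on them, and those originals
form the execution database over which the fine search (optimal local
alignment of the *original* queries, Karlin-Altschul E-values) produces the
ranked report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ccsearch.alignment_engine import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_XDROP,
    evalue,
    smith_waterman,
    ungapped_xdrop_extend,
)
from ccsearch.clustered_db import SEED_LEN, ClusteredDB, Seed, hamming, mismatch_budget
from ccsearch.compression import (
    CompressedDB,
    CompressionParams,
    compress_collection,
    decompress_one,
)
from ccsearch.seq_io import ProteinSequence, reduce_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """All online-phase thresholds (offline ones live in the DB manifest)."""

    t_t: float = 0.80  # query compression threshold
    t_s: float = 0.80  # fragment similarity threshold
    t_c: float = 0.90  # cluster threshold (mirrored from the index)
    seed_len: int = SEED_LEN
    evalue_cutoff: float = 10.0
    hit_score_floor: int = 30
    xdrop: int = DEFAULT_XDROP
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        for name in ("t_t", "t_s", "t_c"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def max_member_dist(self) -> int:
        """Mismatches allowed by T_s on a seed: floor(seed_len * (1 - T_s))."""
        return mismatch_budget(self.seed_len, self.t_s)

    @property
    def max_cluster_radius(self) -> int:
        """Largest representative-member distance T_c allows."""
        return mismatch_budget(self.seed_len, self.t_c)


@dataclass(frozen=True)
class Hit:
    """A query-segment pair surviving seed matching and extension."""

    query_id: str
    segment_id: str
    query_span: tuple[int, int]
    segment_span: tuple[int, int]
    raw_score: int

    def __post_init__(self) -> None:
        if self.raw_score <= 0:
            raise ValueError("hit raw_score must be positive")


@dataclass
class ExecutionDB:
    """Reconstructed originals implicated by hits, plus their recruiters."""

    sequences: list[ProteinSequence]
    origin: dict[str, list[Hit]] = field(default_factory=dict)

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences)


def compress_queries(
    queries: Sequence[ProteinSequence], t_t: float = 0.80
) -> CompressedDB:
    """Compress the query set with similarity threshold T_t."""
    params = CompressionParams(similarity_threshold=t_t)
    return compress_collection(queries, params)


def extract_query_seeds(compressed_queries: CompressedDB) -> list[Seed]:
    """Reduced 10-mers of every query segment, sliding step 1, X skipped."""
    seeds: list[Seed] = []
    for seg_idx, seg in enumerate(compressed_queries.segments):
        reduced = reduce_sequence(seg.residues)
        for p in range(len(reduced) - SEED_LEN + 1):
            window = reduced[p : p + SEED_LEN]
            if "X" in window:
                continue
            seeds.append(Seed(residues=window, location=(seg_idx, p + 1)))
    return seeds


def triangle_bound_pass(d_qr: int, params: SearchParams) -> bool:
    """True iff a cluster at representative distance d_qr needs member scans.

    The lower bound on any member's distance is d_qr minus the cluster
    radius (1 at T_c = 90%); the cluster passes when that bound does not
    exceed the member budget implied by T_s.
    """
    if d_qr < 0:
        raise ValueError("d_qr must be non-negative")
    return d_qr - params.max_cluster_radius <= params.max_member_dist


def _fragment_identity(a: str, b: str) -> float:
    return 1.0 - hamming(a, b) / len(a)


def find_hits(
    query_seeds: Sequence[Seed],
    cdb: ClusteredDB,
    db: CompressedDB,
    qdb: CompressedDB,
    params: SearchParams = SearchParams(),
) -> list[Hit]:
    """Match query seeds against cluster representatives and extend to hits.

    Identical representatives are checked at fragment level (original
    residues, threshold T_s) and then recruit every member; representatives
    within the triangle bound are examined member by member.  Each surviving
    (query segment, pool segment) pair is extended once — ungapped x-drop
    from the seed anchor, then gapped Smith-Waterman over the pair — and
    becomes a hit if the gapped score reaches the hit floor.
    """
    if not cdb.clusters or not query_seeds:
        return []
    rep_mat = np.frombuffer(
        "".join(c.representative.residues for c in cdb.clusters).encode("ascii"),
        dtype=np.uint8,
    ).reshape(len(cdb.clusters), SEED_LEN)
    hits: list[Hit] = []
    pair_cache: dict[tuple[int, int], Optional[Hit]] = {}
    n_examined = 0

    def extend_pair(qseg_idx: int, qpos: int, seg_idx: int, spos: int) -> None:
        nonlocal n_examined
        n_examined += 1
        pair = (qseg_idx, seg_idx)
        if pair in pair_cache:
            return
        qseg = qdb.segments[qseg_idx]
        sseg = db.segments[seg_idx]
        ungapped_score, _, _ = ungapped_xdrop_extend(
            qseg.residues, sseg.residues, qpos, spos, SEED_LEN, xdrop=params.xdrop
        )
        if ungapped_score <= 0:
            # do not cache: another anchor may extend this pair successfully
            return
        aln = smith_waterman(
            qseg.residues,
            sseg.residues,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
        )
        if aln is None or aln.score < params.hit_score_floor:
            pair_cache[pair] = None
            return
        hit = Hit(
            query_id=qseg.id,
            segment_id=sseg.id,
            query_span=aln.query_span,
            segment_span=aln.subject_span,
            raw_score=aln.score,
        )
        pair_cache[pair] = hit
        hits.append(hit)

    for qseed in query_seeds:
        qvec = np.frombuffer(qseed.residues.encode("ascii"), dtype=np.uint8)
        dists = np.count_nonzero(rep_mat != qvec, axis=1)
        for ci in np.nonzero(dists <= params.max_member_dist + params.max_cluster_radius)[0]:
            cluster = cdb.clusters[int(ci)]
            d_qr = int(dists[ci])
            if not triangle_bound_pass(d_qr, params):
                continue
            qseg_idx, qpos = qseed.location
            qfrag = qdb.segments[qseg_idx].residues[qpos - 1 : qpos - 1 + SEED_LEN]
            if d_qr == 0:
                rseg, rpos = cluster.representative.location
                rfrag = db.segments[rseg].residues[rpos - 1 : rpos - 1 + SEED_LEN]
                if _fragment_identity(qfrag, rfrag) >= params.t_s:
                    for member in cluster.members:
                        mseg, mpos = member.location
                        extend_pair(qseg_idx, qpos, mseg, mpos)
                    continue
            # compensation path: representative not identical (or its
            # fragment failed T_s) — members may still be close enough
            for member in cluster.members:
                if hamming(qseed.residues, member.residues) <= params.max_member_dist:
                    mseg, mpos = member.location
                    extend_pair(qseg_idx, qpos, mseg, mpos)
    logger.info(
        "hit finding: %d query seeds, %d member examinations, %d hits",
        len(query_seeds),
        n_examined,
        len(hits),
    )
    return hits


def assemble_execution_db(hits: Sequence[Hit], db: CompressedDB) -> ExecutionDB:
    """Reconstruct every original implicated by a hit segment, once each.

    A hit on a pool segment recruits the segment's own original plus every
    original whose difference scripts reference that segment; output order
    follows the original database order.
    """
    recruits: dict[str, list[Hit]] = {}
    dependents: dict[str, list[str]] = {}
    for i, script in enumerate(db.scripts):
        dependents.setdefault(script.rep_id, []).append(script.owner_id)
    for hit in hits:
        owners = [hit.segment_id] + dependents.get(hit.segment_id, [])
        for owner in owners:
            recruits.setdefault(owner, []).append(hit)
    sequences: list[ProteinSequence] = []
    origin: dict[str, list[Hit]] = {}
    for prov in db.provenance:
        if prov.owner_id in recruits:
            sequences.append(decompress_one(db, prov))
            origin[prov.owner_id] = recruits[prov.owner_id]
    missing = set(recruits) - set(origin)
    if missing:
        raise ValueError(f"hits recruit unknown sequences: {sorted(missing)[:5]}")
    logger.info("execution db: %d sequences from %d hits", len(sequences), len(hits))
    return ExecutionDB(sequences=sequences, origin=origin)


@dataclass(frozen=True)
class ReportRow:
    """One fine-search alignment in conventional 12-column tabular form."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    raw_score: int

    def to_tsv(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pident:.2f}",
                str(self.length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.3g}",
                str(self.raw_score),
            ]
        )


def fine_search(
    original_queries: Sequence[ProteinSequence],
    xdb: ExecutionDB,
    params: SearchParams = SearchParams(),
) -> list[ReportRow]:
    """Optimal local alignment of each original query against the execution DB.

    Rows with E-value above the cutoff are dropped; within a query, rows
    sort by ascending E-value, then descending score, then subject id.
    """
    db_len = xdb.total_residues
    report: list[ReportRow] = []
    for query in original_queries:
        rows: list[ReportRow] = []
        for subject in xdb.sequences:
            aln = smith_waterman(
                query.residues,
                subject.residues,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
            )
            if aln is None:
                continue
            ev = evalue(aln.score, len(query), db_len)
            if ev > params.evalue_cutoff:
                continue
            rows.append(
                ReportRow(
                    query_id=query.id,
                    subject_id=subject.id,
                    pident=100.0 * aln.identity_fraction,
                    length=aln.length,
                    mismatches=aln.mismatches,
                    gap_opens=aln.gap_opens,
                    qstart=aln.query_span[0],
                    qend=aln.query_span[1],
                    sstart=aln.subject_span[0],
                    send=aln.subject_span[1],
                    evalue=ev,
                    raw_score=aln.score,
                )
            )
        rows.sort(key=lambda r: (r.evalue, -r.raw_score, r.subject_id))
        report.extend(rows)
    return report


def run_batch_search(
    queries: Sequence[ProteinSequence],
    db: CompressedDB,
    cdb: ClusteredDB,
    params: SearchParams = SearchParams(),
) -> tuple[list[ReportRow], dict[str, int]]:
    """Full online phase; returns the ranked report plus stage counters."""
    qdb = compress_queries(queries, params.t_t)
    query_seeds = extract_query_seeds(qdb)
    hits = find_hits(query_seeds, cdb, db, qdb, params)
    xdb = assemble_execution_db(hits, db)
    report = fine_search(queries, xdb, params)
    stats = {
        "queries": len(queries),
        "query_residues": sum(len(q) for q in queries),
        "compressed_query_residues": qdb.total_residues,
        "query_seeds": len(query_seeds),
        "hits": len(hits),
        "execution_sequences": len(xdb.sequences),
        "execution_residues": xdb.total_residues,
        "report_rows": len(report),
    }
    for name, value in stats.items():
        logger.info("%s: %d", name, value)
    return report, stats
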