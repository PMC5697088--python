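"""Pairwise alignment primitives shared by every pipeline stage.

Four operations: Needleman-Wunsch global alignment under a linear gap
penalty (redundancy detection during compression), Smith-Waterman local
alignment under affine gaps (the fine search), ungapped x-drop extension
from a seed anchor (hit formation), and Karlin-Altschul E-values for
ranking fine-search alignments.

The global and local dynamic programs are executed by Biopython's
C-accelerated ``PairwiseAligner``; this module fixes the scoring
conventions (gap of length L costs ``gap_penalty * L`` globally and
``gap_open + gap_extend * L`` locally), extracts identity fractions and
1-based spans, and keeps results deterministic by always taking the
aligner's first reported traceback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio import Align

from ccsearch.seq_io import BLOSUM62, ScoringMatrix

#: default gap costs: linear 11 for global alignments, affine 11/1 locally
DEFAULT_GAP_PENALTY = 11
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_XDROP = 20

#: published Karlin-Altschul gapped constants for BLOSUM62, open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

GAP = "-"


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment with gapped rows and 1-based spans."""

    score: int
    aligned_query: str
    aligned_subject: str
    identity_fraction: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: Optional[float] = None

    @property
    def length(self) -> int:
        return len(self.aligned_query)

    @property
    def mismatches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != GAP and b != GAP and a != b
        )

    @property
    def gap_opens(self) -> int:
        n = 0
        for row in (self.aligned_query, self.aligned_subject):
            prev = ""
            for c in row:
                if c == GAP and prev != GAP:
                    n += 1
                prev = c
        return n


def _identity(row_a: str, row_b: str) -> float:
    if not row_a:
        return 0.0
    matches = sum(1 for a, b in zip(row_a, row_b) if a == b and a != GAP)
    return matches / len(row_a)


def _make_aligner(mode: str, open_score: float, extend_score: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = BLOSUM62.biopython
    aligner.open_gap_score = open_score
    aligner.extend_gap_score = extend_score
    return aligner


def needleman_wunsch(
    a: str,
    b: str,
    matrix: ScoringMatrix = BLOSUM62,
    gap_penalty: int = DEFAULT_GAP_PENALTY,
) -> AlignmentResult:
    """Maximum-score global alignment of ``a`` vs ``b`` with linear gaps."""
    if not a or not b:
        raise ValueError("needleman_wunsch requires non-empty sequences")
    aligner = _make_aligner("global", -gap_penalty, -gap_penalty)
    if matrix is not BLOSUM62:
        aligner.substitution_matrix = matrix.biopython
    alignment = aligner.align(a, b)[0]
    row_a, row_b = alignment[0], alignment[1]
    return AlignmentResult(
        score=int(alignment.score),
        aligned_query=row_a,
        aligned_subject=row_b,
        identity_fraction=_identity(row_a, row_b),
        query_span=(1, len(a)),
        subject_span=(1, len(b)),
    )


def nw_similarity(a: str, b: str) -> float:
    """Identity fraction of the default global alignment, in [0, 1].

    This is the similarity used by the 80% redundancy-admission rule:
    identical-residue columns over total alignment columns.
    """
    if a == b:
        return 1.0
    return needleman_wunsch(a, b).identity_fraction


def smith_waterman(
    a: str,
    b: str,
    matrix: ScoringMatrix = BLOSUM62,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Optional[AlignmentResult]:
    """Maximum-score local alignment under affine gaps, or None for no hit.

    A gap of length L costs ``gap_open + gap_extend * L``.  A best score of
    zero (every substitution path negative) is reported as no hit.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    aligner = _make_aligner("local", -(gap_open + gap_extend), -gap_extend)
    if matrix is not BLOSUM62:
        aligner.substitution_matrix = matrix.biopython
    score = aligner.score(a, b)
    if score <= 0:
        return None
    alignment = aligner.align(a, b)[0]
    row_a, row_b = alignment[0], alignment[1]
    blocks_a, blocks_b = alignment.aligned
    q_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    s_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return AlignmentResult(
        score=int(score),
        aligned_query=row_a,
        aligned_subject=row_b,
        identity_fraction=_identity(row_a, row_b),
        query_span=q_span,
        subject_span=s_span,
    )


def ungapped_xdrop_extend(
    query: str,
    subject: str,
    q_anchor: int,
    s_anchor: int,
    anchor_len: int,
    matrix: ScoringMatrix = BLOSUM62,
    xdrop: int = DEFAULT_XDROP,
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Extend an ungapped anchor left and right under the x-drop rule.

    ``q_anchor``/``s_anchor`` are 1-based positions of the first anchor
    residue in each sequence; the anchor region itself is always included.
    Extension in a direction stops once the running score falls more than
    ``xdrop`` below the running maximum; the returned spans are trimmed to
    the maximum-scoring prefix/suffix.  Returns (score, query_span,
    subject_span), spans 1-based inclusive.
    """
    qi, si = q_anchor - 1, s_anchor - 1
    if qi < 0 or si < 0 or qi + anchor_len > len(query) or si + anchor_len > len(subject):
        raise ValueError("anchor out of bounds")
    score = sum(
        matrix.score(query[qi + k], subject[si + k]) for k in range(anchor_len)
    )
    # rightward
    best, run = 0, 0
    best_right = 0
    j = 0
    while qi + anchor_len + j < len(query) and si + anchor_len + j < len(subject):
        run += matrix.score(query[qi + anchor_len + j], subject[si + anchor_len + j])
        j += 1
        if run > best:
            best, best_right = run, j
        elif best - run > xdrop:
            break
    score += best
    # leftward
    best, run = 0, 0
    best_left = 0
    j = 0
    while qi - 1 - j >= 0 and si - 1 - j >= 0:
        run += matrix.score(query[qi - 1 - j], subject[si - 1 - j])
        j += 1
        if run > best:
            best, best_left = run, j
        elif best - run > xdrop:
            break
    score += best
    q_span = (q_anchor - best_left, q_anchor + anchor_len - 1 + best_right)
    s_span = (s_anchor - best_left, s_anchor + anchor_len - 1 + best_right)
    return score, q_span, s_span


def evalue(raw_score: int, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expected hit count ``K * m * n * exp(-lambda * S)``.

    Uses the standard published gapped constants for BLOSUM62 with gap
    open 11 / extend 1 (lambda = 0.267, K = 0.041); monotone decreasing in
    the raw score and linear in both lengths.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * raw_score)
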