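"""Independent reference implementations used only by the tests.

These are deliberately plain, loop-based dynamic programs and exhaustive
enumerations, sharing no code with the package's alignment engine, so they
can serve as oracles for it.
"""

from __future__ import annotations

from ccsearch.seq_io import BLOSUM62


def nw_score_linear(a: str, b: str, gap: int = 11) -> int:
    """Global alignment score, linear gap penalty, plain DP."""
    s = BLOSUM62.score
    prev = [-gap * j for j in range(len(b) + 1)]
    for i in range(1, len(a) + 1):
        cur = [-gap * i]
        for j in range(1, len(b) + 1):
            cur.append(
                max(
                    prev[j - 1] + s(a[i - 1], b[j - 1]),
                    prev[j] - gap,
                    cur[j - 1] - gap,
                )
            )
        prev = cur
    return prev[-1]


def sw_score_affine(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score, affine gaps (length-L gap costs open+L*ext)."""
    s = BLOSUM62.score
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_global_alignments(a: str, b: str):
    """Yield every gapped global alignment (row_a, row_b) of two short strings."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def score_alignment_linear(row_a: str, row_b: str, gap: int = 11) -> int:
    total = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            total -= gap
        else:
            total += BLOSUM62.score(x, y)
    return total


def optimal_global_identities(a: str, b: str, gap: int = 11) -> tuple[int, set[float]]:
    """Exhaustive: best global score and the identity fractions achieving it."""
    best = None
    idents: set[float] = set()
    for ra, rb in enumerate_global_alignments(a, b):
        sc = score_alignment_linear(ra, rb, gap)
        ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-") / len(ra)
        if best is None or sc > best:
            best, idents = sc, {ident}
        elif sc == best:
            idents.add(ident)
    assert best is not None
    return best, idents
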