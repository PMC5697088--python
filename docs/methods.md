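# Methods

This note documents the model behind `ccsearch`, the parameters that
matter, the numerical choices that were genuinely open, and what the test
suite does and does not establish.

## Pipeline model and assumptions

The pipeline assumes that redundancy in protein collections is *local*:
long near-identical blocks shared between sequences that are otherwise
unrelated. Compression therefore operates on subsequences, not whole
records, and the search index is built over the non-redundant residue
pool so that each shared block is seeded and matched once. The final
report is always computed by optimal local alignment of the *original*
queries against fully reconstructed original sequences; the coarse stages
can only lose hits, never invent or distort them. Consequently every
coarse-stage design choice below trades sensitivity against work done,
while alignment coordinates, identities and scores in the report are
exact by construction.

## Compression

Sequences are processed in input order; earlier sequences become
representatives for later ones. A scan position whose 5-mer matches an
indexed word of the retained pool triggers a global alignment
(Needleman–Wunsch, BLOSUM62, linear gap 11) of the two downstream
subsequences, from the word start to each sequence's end. Similarity is
the identity fraction over alignment columns. The removed region is the
longest aligned prefix that (a) ends on a match column, (b) consumes at
least 15 query residues, and (c) has prefix identity above the threshold;
this reproduces front / middle / rear block removal without a span rule
the data cannot support.

Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| key length | 5 residues | exact-match anchor for redundancy detection |
| similarity threshold | 0.80 | identity a span must exceed to be removed (T_t for query sets, configurable) |
| minimum removable span | 15 residues (3 × key length) | floor preventing fragmentation into confetti over chance 5-mer matches |

Thresholds are strict (`similarity > T`) except that exact matches
(`similarity == 1.0`) are always admitted, so a threshold of 1.0 removes
verbatim spans only. Difference-script offsets count residues in the
*representative* span: an operation's digit is the distance from the
previous operation's position (or the span start) to the affected
representative residue — for insertions, to the residue before which the
new one is placed. This convention makes encode/decode exact inverses,
which the suite checks on hundreds of randomized pairs. Scripts always
reference a retained pool segment, never another script, so decoding is
single-hop.

The on-disk form is a FASTA pool plus a line-oriented text sidecar with
two record types: `S` rows (one per script: owner, slot, representative
coordinates, edit list in the `r6L,r8A,…` syntax) and `P` rows (one per
original sequence: the ordered literal/script assembly plan, literals as
run lengths into the sequence's own residual segment). Descriptions of
fully-removed sequences are not preserved across a save/load cycle;
residues, ids and order are bit-exact.

## Clustered index

Key admission scores a window by summing, per residue, the *maximum*
BLOSUM62 diagonal within the residue's reduced-alphabet group. With the
threshold T = 39 and window lengths 6–9, information-dense windows
qualify short (any six of F/Y/W score 66) and low-complexity stretches
never qualify (poly-A peaks at 36 across nine residues). The scan
registers the shortest qualifying window at each position and resumes
after it, so registered keys never overlap. Seeds require five residues
of left context inside the segment; windows touching an X, and keys whose
seed window would cross a segment boundary, are dropped rather than
padded.

Clustering is greedy first-fit in discovery order, scoped per originating
key: a seed joins the first cluster of its key whose *representative* is
within Hamming distance 1 (the 90% threshold on ten residues), else
founds a new cluster. Greedy first-fit is deterministic and guarantees
the radius invariant the online filter depends on; it does not minimize
cluster count, which the search does not need. Mismatch budgets derived
from thresholds are computed as `floor(len * (1 - T) + 1e-9)`; the
epsilon matters because `1 - 0.9` is not exactly `0.1` in binary floating
point and a bare floor would silently shrink every budget by one.

## Online search

| parameter | default | meaning |
|---|---|---|
| T_t | 0.80 | query-set compression threshold |
| T_s | 0.80 | fragment identity a seed match must reach → member budget floor(10·0.2) = 2 mismatches |
| T_c | 0.90 | cluster threshold, mirrored from the index manifest → radius 1 |
| x-drop | 20 raw score units | ungapped extension termination |
| hit floor | 30 raw score | minimum gapped score for a hit |
| gap model | 11 linear (global), 11/1 affine (local) | BLOSUM62 community defaults |
| E-value constants | λ = 0.267, K = 0.041 | published gapped BLOSUM62 11/1 values |
| E-value cutoff | 10 | report filter |

Query seeds slide with step 1 (maximal sensitivity, the BLAST
convention). A cluster is examined when `d(S_q,S_r) − radius ≤ budget`,
i.e. `d_qr ≤ 3` at defaults; by the triangle inequality no member within
the 2-mismatch budget can hide in a pruned cluster, and the suite
verifies this against a brute-force member scan on a thousand random
instances. For an identical representative whose original fragment
passes T_s, all members are recruited without individual distance checks;
otherwise members are examined one by one. Hits found through the
compensation path are scored identically to direct ones.

Gapped extension runs full Smith–Waterman on the (query segment, pool
segment) pair rather than a banded x-drop: segments at execution-database
scale are short enough that exactness is cheaper than the bookkeeping.
Each pair is aligned once and cached; a failed *ungapped* pre-extension
does not veto the pair, since a different anchor may extend it.

The execution database contains, for every hit segment, the segment's own
original sequence plus every original whose scripts reference it, each
reconstructed in full, deduplicated, in original database order. The fine
search aligns original queries against it with affine Smith–Waterman;
E-values use the query length and the execution database's total residue
count, so they are comparable across queries of one batch but not across
batches with different hit sets. Ties sort by ascending E-value, then
descending score, then subject id.

## Alignment engine

Global and local dynamic programs are executed by Biopython's
C-accelerated `PairwiseAligner` under the package's scoring conventions
(gap of length L costs 11·L globally, 11 + L locally); the module fixes
identity/span extraction and determinism by always taking the aligner's
first reported traceback. The test suite holds both aligners to
independently written plain-Python dynamic programs on hundreds of random
pairs, and to exhaustive alignment enumeration on short strings, so the
wrapper's conventions — not just Biopython's correctness — are what is
certified. Traceback tie-breaking among co-optimal alignments follows the
aligner's internal deterministic order; identity fractions of co-optimal
alignments can differ in principle, which is why similarity-threshold
comparisons in compression use strict inequalities away from 1.0.

## Synthetic data

The generator emulates one property of real databases: families sharing
a mutated block (substitutions at 5%/position, single-residue indels at
1%/position by default — comfortably inside the 80% admission threshold)
embedded in uniform random background. It deliberately does not model
residue composition bias, domain architectures, low-complexity regions or
phylogenetic correlation. Passing tests therefore certify the machinery
(losslessness, filter completeness, recall of planted homologs), not
search sensitivity on real proteomes; composition bias in particular
would change key densities and cluster sizes, though not correctness.
Defaults used by the deeper end-to-end checks: 100 families × 5 members,
110-residue sequences with 40-residue blocks, 25 exact-copy queries —
sizes chosen so the whole suite exercises every stage in well under a
minute while the 500-sequence recall check still runs through a
non-trivial index.

## Degenerate inputs and edge rules

Empty FASTA files parse to empty collections (with a warning); records
with empty sequences, duplicate ids, or residues outside the 20-letter
alphabet plus X are rejected at parse time (ambiguity codes B/Z/U/O are
refused rather than silently mapped). X maps to its own reduced symbol,
scores −1 in key admission, and is excluded from seeds on both the
database and query sides. Sequences shorter than the key length pass
through compression untouched. Smith–Waterman results with score 0 are
reported as "no hit". An empty query set, or a query sharing no seed
with any cluster, produces an empty report without error.

## Known limitations

- Compression is single-pass and order-dependent: the first occurrence
  of a block becomes the representative, and within-sequence (self)
  redundancy is not folded.
- Greedy clustering and first-fit span matching are not optimal, only
  deterministic; a different input order yields a different (equally
  valid) pool and index.
- E-values use fixed published constants rather than composition-based
  recalculation, and multiple HSPs per pair are not combined.
- The index is static; updating a compressed database incrementally is
  out of scope.
- Single-threaded throughout; the intended scale is desk-sized
  collections, not full reference databases.
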