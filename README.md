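# ccsearch

Batch protein homology search over a losslessly compressed, clustered
sequence database.

## The problem

Searching a set of protein queries against a large database with a
BLAST-style tool repeats a great deal of work: real databases are locally
redundant (domains, paralogs, strain variants share long near-identical
blocks), and naive batch search rescans that shared sequence once per
query. `ccsearch` is a coarse-to-fine pipeline for people who run many
protein queries at once and want the seed-matching stage to touch each
redundant block only once, without giving up an exact final alignment.

## The method

**Offline (per database).** The database is compressed in input order:
every 5-residue word of already-retained sequence is indexed in a
key-entry map; when a later sequence reaches a matching word, the two
downstream subsequences are globally aligned (Needleman–Wunsch, BLOSUM62)
and the longest aligned prefix whose identity exceeds the similarity
threshold (80%) is deleted and replaced by a *difference script* — the
representative's coordinates plus replace/insert/delete edits, e.g.
`a,15,43` + `r6L,r8A,r3V,i5D` — so the original residues can always be
reconstructed exactly. The surviving segment pool is then scanned for
high-information *keys*: windows of 6–9 residues whose grouped-maximum
BLOSUM62 score Σᵢ maxₐ∈group(rᵢ) s(a,a) exceeds T = 39, under the
ten-group reduced amino-acid alphabet

    (A) (K,R) (E,D,N,Q) (C) (G) (H) (I,L,V,M) (F,Y,W) (P) (S,T)

(`YKWVN` scores 38 and is rejected; `YKWVNK` scores 43 and is a key).
Each key spawns a 10-residue *seed* (5 residues of left context + the
first 5 key residues, reduced alphabet). Seeds from the same key are
greedily clustered at 90% similarity, i.e. Hamming radius 1 around a
representative, yielding three maps: key→occurrences, representative
seed→cluster, cluster→member locations.

**Online (per query batch).** The query set is compressed the same way
(threshold T_t), scanned into sliding 10-mer seeds, and each query seed
S_q is compared with cluster representatives S_r. An identical
representative whose original 10-residue fragment passes the 80% identity
check recruits every cluster member. A representative at Hamming distance
d(S_q,S_r) > 0 may still hide a qualifying member S_m, because

    d(S_q,S_m) ≥ d(S_q,S_r) − d(S_r,S_m)   with   d(S_r,S_m) ≤ 1,

so any cluster with d(S_q,S_r) ≤ 3 is examined member by member — this
triangle-inequality compensation makes the representative-level filter
provably lossless down to 2 mismatches. Surviving members are extended
(ungapped x-drop, then gapped Smith–Waterman) into hits; every original
sequence whose scripts depend on a hit segment is reconstructed into a
small *execution database*; and the original (uncompressed) queries are
aligned against it with affine-gap Smith–Waterman and Karlin–Altschul
E-values to produce the final ranked report.

## Worked example

```bash
ccsearch fixture --out-dir fix --families 10 --members 5 --queries 5 --seed 42
ccsearch makedb  --input fix/db.fasta --out-dir artifacts
ccsearch search  --query fix/queries.fasta --db artifacts --out report.tsv
```

prints

```
fixture: 50 database sequences, 5 queries -> fix
makedb: 50 sequences -> 50 segments, 533 seeds in 533 clusters -> artifacts
search: 72 alignments for 5 queries -> report.tsv
```

and the top of `report.tsv` reads

```
# query_id  subject_id  pident  length  mismatches  gap_opens  qstart  qend  sstart  send  evalue    raw_score
q0          f0m2        100.00  120     0           0          1       120   1       120   1.6e-78   707
q0          f0m0        84.31   51      8           0          59      109   64      114   6.61e-24  236
q0          f0m3        73.77   61      11          1          60      120   12      67    1.92e-23  232
```

Query `q0` is a verbatim copy of database sequence `f0m2`, and the fine
search ranks that sequence first with 100% identity over its full 120
residues (raw Smith–Waterman score 707, E ≈ 1.6·10⁻⁷⁸); the remaining
rows are the other members of family 0, recovered through the shared
mutated block they were compressed against (50–61 aligned columns at
74–93% identity). The columns follow the conventional 12-column tabular
alignment layout.

The library surface mirrors the pipeline: `compress_collection` /
`decompress` (lossless compression), `build_clustered_db` (the three
maps), `run_batch_search` (the online phase), and
`synthetic_data.make_database` for reproducible test collections.

## Layout

```
src/ccsearch/
  seq_io.py            FASTA I/O, BLOSUM62, the 10-group reduced alphabet
  alignment_engine.py  NW / SW / x-drop extension / E-values
  compression.py       key-entry map, difference scripts, (de)compression
  clustered_db.py      key finding, seed generation, Hamming clustering
  batch_search.py      query seeding, triangle filter, hits, fine search
  synthetic_data.py    family generator with planted ground truth
  cli.py               the `ccsearch` console entry point
docs/methods.md        model, parameters, numerical choices, limitations
```
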