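"""Key finding, seed generation and Hamming clustering over the segment pool.

Candidate keys are short windows (6-9 residues) of pool segments whose
grouped-maximum BLOSUM62 score exceeds a threshold T (default 39): each
residue contributes the largest diagonal score within its reduced-alphabet
group, so high-information windows qualify at length 6 while low-complexity
stretches never qualify at all.  The scan registers the shortest qualifying
window at each position and resumes past it.

Each key occurrence spawns one 10-residue seed: the five residues preceding
the key start plus the first five key residues, expressed in the reduced
alphabet.  Seeds from the same key are greedily clustered: a seed joins the
first cluster whose representative lies within Hamming distance 1 (the 90%
similarity threshold on ten residues), otherwise it founds a new cluster.
The resulting structure is three maps: Map1 key->occurrences, Map2
representative-seed->(cluster id, location), Map3 cluster id->member
locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from ccsearch.compression import CompressedDB, KeyEntryMap
from ccsearch.seq_io import REDUCED, ProteinSequence, ReducedAlphabet

logger = logging.getLogger(__name__)

SEED_LEN = 10
#: residues of left context a key needs before it can spawn a seed
SEED_LEFT = 5

DEFAULT_CLUSTER_THRESHOLD = 0.90


def mismatch_budget(length: int, similarity_threshold: float) -> int:
    """floor(length * (1 - threshold)), robust to float representation.

    At 90% on ten residues this is 1 mismatch; at 80%, 2 mismatches.
    """
    return int(length * (1 - similarity_threshold) + 1e-9)


@dataclass(frozen=True)
class KeyFinderParams:
    min_key_len: int = 6
    max_key_len: int = 9
    score_threshold: int = 39  # T: empirical key-admission threshold
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD  # T_c

    def __post_init__(self) -> None:
        if not (1 <= self.min_key_len <= self.max_key_len):
            raise ValueError("need 1 <= min_key_len <= max_key_len")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if not (0 < self.cluster_threshold <= 1):
            raise ValueError("cluster_threshold must be in (0, 1]")

    @property
    def max_cluster_radius(self) -> int:
        """Largest representative-member Hamming distance the threshold allows."""
        return mismatch_budget(SEED_LEN, self.cluster_threshold)


@dataclass(frozen=True)
class Seed:
    """A reduced-alphabet 10-mer anchored at a pool-segment location."""

    residues: str
    location: tuple[int, int]  # (segment index, 1-based start of first residue)
    key: Optional[str] = None  # reduced key that spawned it (None: query seed)

    def __post_init__(self) -> None:
        if len(self.residues) != SEED_LEN:
            raise ValueError(f"seed must have {SEED_LEN} residues")


@dataclass
class SeedCluster:
    cluster_id: int
    representative: Seed
    members: list[Seed] = field(default_factory=list)


def key_score(subseq: str, alphabet: ReducedAlphabet = REDUCED) -> int:
    """Grouped-maximum BLOSUM62 score of a candidate key window.

    Each residue contributes the highest diagonal score among its group's
    members (e.g. any of F/Y/W contributes W's 11).
    """
    if not subseq:
        raise ValueError("empty subsequence")
    total = 0
    for i, c in enumerate(subseq):
        try:
            total += alphabet.group_max_diag[c]
        except KeyError:
            raise ValueError(f"unknown residue {c!r} at position {i + 1}") from None
    return total


def find_keys(
    segments: Sequence[ProteinSequence],
    params: KeyFinderParams = KeyFinderParams(),
    alphabet: ReducedAlphabet = REDUCED,
) -> KeyEntryMap:
    """Scan the pool and register score-qualifying keys (Map1).

    At each position the shortest window of length 6-9 whose score exceeds
    T is registered (stored in reduced form, located in original
    coordinates); the scan then resumes immediately after that window so
    keys never start inside a registered key.  Windows containing X never
    qualify.
    """
    kmap = KeyEntryMap(key_len=None)  # variable-length keys
    diag = alphabet.group_max_diag
    for seg_idx, seg in enumerate(segments):
        res = seg.residues
        p = 0
        while p + params.min_key_len <= len(res):
            registered = False
            score = sum(diag[c] for c in res[p : p + params.min_key_len - 1])
            for length in range(params.min_key_len, params.max_key_len + 1):
                if p + length > len(res):
                    break
                score += diag[res[p + length - 1]]
                if "X" in res[p : p + length]:
                    break
                if score > params.score_threshold:
                    kmap.add(alphabet.reduce_sequence(res[p : p + length]), seg_idx, p + 1)
                    p += length
                    registered = True
                    break
            if not registered:
                p += 1
    return kmap


def generate_seeds(
    map1: KeyEntryMap,
    segments: Sequence[ProteinSequence],
    alphabet: ReducedAlphabet = REDUCED,
) -> list[Seed]:
    """One seed per key occurrence with enough left context.

    The seed covers segment positions [p-5, p+4] for a key starting at p;
    occurrences with p <= 5 (or an X inside the window) produce nothing.
    """
    seeds: list[Seed] = []
    for key in map1.keys():
        for entry in map1.occurrences(key):
            p = entry.start_pos
            if p <= SEED_LEFT:
                continue
            res = segments[entry.seq_index].residues
            window = res[p - SEED_LEFT - 1 : p + SEED_LEN - SEED_LEFT - 1]
            if len(window) < SEED_LEN or "X" in window:
                continue
            seeds.append(
                Seed(
                    residues=alphabet.reduce_sequence(window),
                    location=(entry.seq_index, p - SEED_LEFT),
                    key=key,
                )
            )
    return seeds


def hamming(a: str, b: str) -> int:
    """Count of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


Map2 = dict[str, list[tuple[int, tuple[int, int]]]]
Map3 = dict[int, list[tuple[int, int]]]


def cluster_seeds(
    seeds: Sequence[Seed],
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> tuple[Map2, Map3, list[SeedCluster]]:
    """Greedy first-fit clustering of seeds, scoped per originating key.

    In discovery order a seed joins the first existing cluster of its own
    key whose *representative* is within the radius implied by the
    threshold (Hamming distance 1 at 90% on ten residues), else founds a
    new cluster.  Returns (Map2, Map3, clusters); Map3 member lists include
    the representative's own location.
    """
    radius = mismatch_budget(SEED_LEN, cluster_threshold)
    clusters: list[SeedCluster] = []
    by_key: dict[Optional[str], list[SeedCluster]] = {}
    for seed in seeds:
        placed = False
        for cluster in by_key.setdefault(seed.key, []):
            if hamming(cluster.representative.residues, seed.residues) <= radius:
                cluster.members.append(seed)
                placed = True
                break
        if not placed:
            cluster = SeedCluster(cluster_id=len(clusters), representative=seed, members=[seed])
            clusters.append(cluster)
            by_key[seed.key].append(cluster)
    map2: Map2 = {}
    map3: Map3 = {}
    for cluster in clusters:
        rep = cluster.representative
        map2.setdefault(rep.residues, []).append((cluster.cluster_id, rep.location))
        map3[cluster.cluster_id] = [m.location for m in cluster.members]
    return map2, map3, clusters


@dataclass
class ClusteredDB:
    """The offline search index: Map1/Map2/Map3 over a compressed pool."""

    map1: KeyEntryMap
    map2: Map2
    map3: Map3
    clusters: list[SeedCluster]
    params: KeyFinderParams

    @property
    def n_seeds(self) -> int:
        return sum(len(v) for v in self.map3.values())


def build_clustered_db(
    db: CompressedDB, params: KeyFinderParams = KeyFinderParams()
) -> ClusteredDB:
    """find_keys -> generate_seeds -> cluster_seeds over a compressed pool."""
    map1 = find_keys(db.segments, params)
    seeds = generate_seeds(map1, db.segments)
    map2, map3, clusters = cluster_seeds(seeds, params.cluster_threshold)
    logger.info(
        "clustered db: %d keys, %d seeds, %d clusters",
        len(list(map1.keys())),
        len(seeds),
        len(clusters),
    )
    return ClusteredDB(map1=map1, map2=map2, map3=map3, clusters=clusters, params=params)


# ---------------------------------------------------------------------------
# persistence: three TSVs + YAML manifest


def save_clustered_db(cdb: ClusteredDB, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "map1.tsv", "w") as fh:
        for key in cdb.map1.keys():
            for entry in cdb.map1.occurrences(key):
                fh.write(f"{key}\t{entry.seq_index}\t{entry.start_pos}\n")
    with open(directory / "map2.tsv", "w") as fh:
        for cluster in cdb.clusters:
            rep = cluster.representative
            fh.write(
                f"{rep.residues}\t{cluster.cluster_id}\t{rep.location[0]}\t{rep.location[1]}"
                f"\t{rep.key or '-'}\n"
            )
    with open(directory / "map3.tsv", "w") as fh:
        for cluster in cdb.clusters:
            members = ";".join(
                f"{m.location[0]}:{m.location[1]}:{m.residues}" for m in cluster.members
            )
            fh.write(f"{cluster.cluster_id}\t{members}\n")
    with open(directory / "cluster_params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "min_key_len": cdb.params.min_key_len,
                "max_key_len": cdb.params.max_key_len,
                "score_threshold": cdb.params.score_threshold,
                "cluster_threshold": cdb.params.cluster_threshold,
                "seed_len": SEED_LEN,
            },
            fh,
        )


def load_clustered_db(directory: str | Path) -> ClusteredDB:
    directory = Path(directory)
    with open(directory / "cluster_params.yaml") as fh:
        raw = yaml.safe_load(fh)
    if raw.get("seed_len", SEED_LEN) != SEED_LEN:
        raise ValueError(f"unsupported seed length {raw['seed_len']}")
    params = KeyFinderParams(
        min_key_len=raw["min_key_len"],
        max_key_len=raw["max_key_len"],
        score_threshold=raw["score_threshold"],
        cluster_threshold=raw["cluster_threshold"],
    )
    map1 = KeyEntryMap(key_len=None)
    with open(directory / "map1.tsv") as fh:
        for line in fh:
            key, seg, pos = line.rstrip("\n").split("\t")
            map1.add(key, int(seg), int(pos))
    reps: dict[int, Seed] = {}
    with open(directory / "map2.tsv") as fh:
        for line in fh:
            residues, cid, seg, pos, key = line.rstrip("\n").split("\t")
            reps[int(cid)] = Seed(
                residues=residues,
                location=(int(seg), int(pos)),
                key=None if key == "-" else key,
            )
    map3: Map3 = {}
    clusters: list[SeedCluster] = []
    with open(directory / "map3.tsv") as fh:
        for line in fh:
            cid_s, items = line.rstrip("\n").split("\t")
            cid = int(cid_s)
            rep = reps[cid]
            members = []
            for item in items.split(";"):
                seg, pos, residues = item.split(":")
                members.append(Seed(residues=residues, location=(int(seg), int(pos)), key=rep.key))
            map3[cid] = [m.location for m in members]
            clusters.append(SeedCluster(cluster_id=cid, representative=rep, members=members))
    clusters.sort(key=lambda c: c.cluster_id)
    map2: Map2 = {}
    for cluster in clusters:
        rep = cluster.representative
        map2.setdefault(rep.residues, []).append((cluster.cluster_id, rep.location))
    return ClusteredDB(map1=map1, map2=map2, map3=map3, clusters=clusters, params=params)
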