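"""Key-entry maps, difference scripts, and the lossless-compression round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsearch.compression import (
    CompressionParams,
    CorruptionError,
    DiffScript,
    EditOp,
    apply_ops,
    build_key_entry_map,
    compress_collection,
    decode_diff_script,
    decompress,
    encode_diff_script,
    format_ops,
    load_compressed,
    parse_ops,
    save_compressed,
)
from ccsearch.alignment_engine import nw_similarity
from ccsearch.seq_io import ProteinSequence, STANDARD_RESIDUES
from ccsearch.synthetic_data import FamilySpec, make_database

from conftest import random_protein


def _seq(i, residues):
    return ProteinSequence(id=f"s{i}", residues=residues)


class TestKeyEntryMap:
    def test_window_count_is_length_minus_key_len_plus_one(self):
        kmap = build_key_entry_map([_seq(0, "MKTAYW")], key_len=5)
        assert kmap.n_entries == 2
        assert [e.start_pos for e in kmap.occurrences("MKTAY")] == [1]
        assert [e.start_pos for e in kmap.occurrences("KTAYW")] == [2]

    def test_shared_word_chains_two_entries(self):
        kmap = build_key_entry_map(
            [_seq(0, "AAASERGKWWW"), _seq(1, "PPPSERGKYYY")], key_len=5
        )
        entries = list(kmap.occurrences("SERGK"))
        assert [(e.seq_index, e.start_pos) for e in entries] == [(0, 4), (1, 4)]
        # the chain is linked, acyclic, and ends
        assert entries[0].next is entries[1] and entries[1].next is None

    def test_short_sequence_contributes_nothing(self):
        kmap = build_key_entry_map([_seq(0, "MKTA")], key_len=5)
        assert kmap.n_entries == 0


class TestEditOps:
    def test_parse_printed_script_syntax(self):
        ops = parse_ops("r6L, r8A, r3V, i5D")
        assert [op.kind for op in ops] == ["r", "r", "r", "i"]
        assert [op.offset for op in ops] == [6, 8, 3, 5]
        assert [op.residue for op in ops] == ["L", "A", "V", "D"]

    def test_format_parse_round_trip(self):
        ops = (EditOp("r", 4, "W"), EditOp("d", 2), EditOp("i", 1, "K"))
        assert tuple(parse_ops(format_ops(ops))) == ops

    def test_malformed_op_rejected(self):
        with pytest.raises(ValueError, match="q7"):
            parse_ops("r6L, q7")

    def test_residue_presence_matches_kind(self):
        with pytest.raises(ValueError):
            EditOp("d", 3, "W")
        with pytest.raises(ValueError):
            EditOp("r", 3)


class TestDiffScripts:
    def test_identical_spans_empty_ops(self):
        script = encode_diff_script("MKTAYIAKQRWEDNQ", "MKTAYIAKQRWEDNQ", "a", 1, "b")
        assert script.ops == ()
        assert decode_diff_script("MKTAYIAKQRWEDNQ", script) == "MKTAYIAKQRWEDNQ"

    def test_single_replacement_offset_counts_from_span_start(self):
        rep, removed = "AAAAAAAAAA", "AAAWAAAAAA"
        script = encode_diff_script(rep, removed, "a", 1, "b")
        assert script.ops == (EditOp("r", 4, "W"),)
        assert decode_diff_script(rep, script) == removed

    def test_leading_deletion(self):
        script = DiffScript("a", 1, 10, (EditOp("d", 1),), "b")
        assert decode_diff_script("WKTAYIAKQR", script) == "KTAYIAKQR"

    def test_below_threshold_refused(self):
        with pytest.raises(ValueError, match="threshold"):
            encode_diff_script("AAAAAAAAAA", "WWWWWWWWWW", "a", 1, "b")

    def test_offset_past_span_end_is_corruption(self):
        script = DiffScript("a", 1, 5, (EditOp("r", 9, "W"),), "b")
        with pytest.raises(CorruptionError):
            decode_diff_script("MKTAY", script)

    def test_decode_inverts_encode_on_random_similar_pairs(self, rng):
        for _ in range(300):
            n = int(rng.integers(15, 60))
            rep = random_protein(rng, n)
            removed = list(rep)
            for k in rng.choice(n, size=max(1, n // 10), replace=False):
                removed[k] = STANDARD_RESIDUES[rng.integers(0, 20)]
            removed = "".join(removed)
            if nw_similarity(rep, removed) <= 0.8:
                continue
            script = encode_diff_script(rep, removed, "a", 1, "b")
            assert decode_diff_script(rep, script) == removed

    @given(st.text(alphabet=STANDARD_RESIDUES, min_size=1, max_size=30))
    @settings(max_examples=50)
    def test_apply_ops_empty_is_identity(self, span):
        assert apply_ops(span, ()) == span


class TestCompressCollection:
    def test_exact_duplicate_collapses_to_whole_span_script(self):
        s = "MKTAYIWKQRHEDNQKRWYF"
        db = compress_collection([_seq(0, s), _seq(1, s)])
        assert len(db.segments) == 1
        assert len(db.scripts) == 1
        script = db.scripts[0]
        assert script.ops == () and script.owner_slot == "whole"
        assert (script.start, script.end) == (1, len(s))

    def test_redundancy_patterns_front_middle_rear(self, rng):
        # a shared block placed at the rear, middle and front of followers;
        # an exact copy of the founder disappears entirely, and an unrelated
        # sequence survives untouched
        block = random_protein(rng, 40)
        flanks = [random_protein(rng, 30) for _ in range(5)]
        q1 = _seq(1, flanks[0] + block)
        q2 = _seq(2, flanks[1] + block)  # rear block removed
        q3 = _seq(3, flanks[2] + block + flanks[3])  # middle removed, flanks concatenated
        q4 = _seq(4, block + flanks[4])  # front removed
        q5 = _seq(5, flanks[0] + block)  # exact copy: completely removed
        q6 = _seq(6, random_protein(rng, 70))  # completely reserved
        db = compress_collection([q1, q2, q3, q4, q5, q6])
        residual = {seg.id: seg.residues for seg in db.segments}
        assert residual["s1"] == q1.residues
        assert residual["s2"] == flanks[1]
        assert residual["s3"] == flanks[2] + flanks[3]
        assert residual["s4"] == flanks[4]
        assert "s5" not in residual
        assert residual["s6"] == q6.residues
        slots = {s.owner_id: s.owner_slot for s in db.scripts}
        assert slots == {"s2": "suffix", "s3": "middle", "s4": "prefix", "s5": "whole"}
        assert decompress(db) == [q1, q2, q3, q4, q5, q6]

    def test_unrelated_sequences_untouched(self, rng):
        # brute-force check that no qualifying shared region exists, then
        # confirm compression leaves the pool identical to the input
        seqs = [_seq(i, random_protein(rng, 50)) for i in range(8)]
        shared = set()
        for i, a in enumerate(seqs):
            for b in seqs[:i]:
                for p in range(46):
                    if a.residues[p : p + 5] in b.residues:
                        shared.add((b.id, a.id))
        assert not shared, "seeded generator unexpectedly produced a shared 5-mer"
        db = compress_collection(seqs)
        assert [s.residues for s in db.segments] == [s.residues for s in seqs]
        assert db.scripts == []

    def test_lossless_round_trip_across_thresholds(self, family_collection):
        for threshold in (0.4, 0.6, 0.8, 1.0):
            db = compress_collection(
                family_collection, CompressionParams(similarity_threshold=threshold)
            )
            assert decompress(db) == list(family_collection)

    def test_pool_residues_monotone_in_threshold(self, family_collection):
        sizes = [
            compress_collection(
                family_collection, CompressionParams(similarity_threshold=t)
            ).total_residues
            for t in (0.4, 0.6, 0.8, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_threshold_one_removes_only_verbatim_spans(self, rng):
        # at threshold 1.0 every removed span is an exact copy of its
        # representative span (scripts carry zero edits), and collections
        # with no shared subsequence pass through untouched
        base = random_protein(rng, 60)
        near = base[:30] + ("A" if base[30] != "A" else "W") + base[31:]
        seqs = [_seq(0, base), _seq(1, base), _seq(2, near)]
        db = compress_collection(seqs, CompressionParams(similarity_threshold=1.0))
        assert all(script.ops == () for script in db.scripts)
        assert "s1" not in {seg.id for seg in db.segments}  # exact duplicate gone
        assert decompress(db) == seqs
        distinct = [_seq(i, random_protein(rng, 50)) for i in range(5)]
        db2 = compress_collection(distinct, CompressionParams(similarity_threshold=1.0))
        assert [s.residues for s in db2.segments] == [s.residues for s in distinct]

    def test_script_edit_load_respects_admission_threshold(self, family_collection):
        db = compress_collection(family_collection)
        for script in db.scripts:
            span_len = script.end - script.start + 1
            mutating = sum(1 for op in script.ops if op.kind in "ri")
            assert mutating <= 0.25 * span_len  # identity > 0.8 bounds r+i ops

    def test_sub_key_length_sequences_pass_through(self):
        db = compress_collection([_seq(0, "MKT")])
        assert decompress(db) == [_seq(0, "MKT")]


class TestPersistence:
    def test_sidecar_round_trip(self, tmp_path, family_collection):
        db = compress_collection(family_collection)
        save_compressed(db, tmp_path / "pool.fasta", tmp_path / "scripts.tsv")
        back = load_compressed(tmp_path / "pool.fasta", tmp_path / "scripts.tsv")
        assert back.params == db.params
        assert [s.residues for s in back.segments] == [s.residues for s in db.segments]
        assert back.scripts == db.scripts
        assert [(p.owner_id, p.parts) for p in back.provenance] == [
            (p.owner_id, p.parts) for p in db.provenance
        ]
        assert [(s.id, s.residues) for s in decompress(back)] == [
            (s.id, s.residues) for s in family_collection
        ]

    def test_sidecar_is_line_oriented_text(self, tmp_path, family_collection):
        db = compress_collection(family_collection)
        save_compressed(db, tmp_path / "pool.fasta", tmp_path / "scripts.tsv")
        lines = (tmp_path / "scripts.tsv").read_text().splitlines()
        assert lines[0].startswith("# ccsearch-compressed v1")
        kinds = {line.split("\t")[0] for line in lines[1:]}
        assert kinds <= {"S", "P"}

    def test_dangling_script_reference_is_corruption(self, tmp_path, family_collection):
        db = compress_collection(family_collection)
        save_compressed(db, tmp_path / "pool.fasta", tmp_path / "scripts.tsv")
        text = (tmp_path / "scripts.tsv").read_text()
        mutated = []
        for line in text.splitlines():
            if line.startswith("S\t"):
                fields = line.split("\t")
                loc = fields[4].rsplit(",", 2)
                fields[4] = ",".join(["no_such_segment", loc[1], loc[2]])
                line = "\t".join(fields)
            mutated.append(line)
        (tmp_path / "scripts.tsv").write_text("\n".join(mutated) + "\n")
        broken = load_compressed(tmp_path / "pool.fasta", tmp_path / "scripts.tsv")
        with pytest.raises(CorruptionError):
            decompress(broken)


class TestLosslessProperty:
    def test_random_families_round_trip_all_thresholds(self):
        for seed in range(10):
            seqs, _ = make_database(
                FamilySpec(
                    n_families=2,
                    members_per_family=3,
                    rep_length=70,
                    block_length=30,
                    substitution_rate=0.06,
                    indel_rate=0.02,
                    placement=("prefix", "middle", "suffix", "whole")[seed % 4],
                    rng_seed=seed,
                )
            )
            for threshold in (0.4, 0.8):
                db = compress_collection(
                    seqs, CompressionParams(similarity_threshold=threshold)
                )
                assert decompress(db) == seqs
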