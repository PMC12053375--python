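"""Database sanitization, deduplication, and volume splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnahomkit import seqdb
from rnahomkit.seqdb import (
    DROP,
    DbStats,
    InvalidRecordError,
    SeqRecord,
    build_database,
    dedup_stream,
    read_fasta,
    sanitize_record,
    split_volumes,
    write_fasta,
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("acgu", "ACGT"),
        ("AC-G.RYacgt", "ACNGNNNACGT"),
        ("ACGT", "ACGT"),
        ("nNxX*", "NNNNN"),
    ],
)
def test_sanitize_maps_to_dna_alphabet(raw, expected):
    assert sanitize_record(SeqRecord("r", raw)).seq == expected


def test_sanitize_drops_over_length_cap():
    assert sanitize_record(SeqRecord("r", "A" * 11), max_len=10) is DROP
    assert sanitize_record(SeqRecord("r", "A" * 10), max_len=10).seq == "A" * 10


def test_sanitize_rejects_empty_sequence():
    with pytest.raises(InvalidRecordError):
        sanitize_record(SeqRecord("r", ""))


@given(st.text(alphabet=st.characters(codec="ascii"), min_size=1, max_size=50))
@settings(max_examples=200, deadline=None)
def test_sanitize_is_idempotent_and_closed(raw):
    """Any sanitized output is over {A,C,G,T,N} and a fixed point."""
    once = sanitize_record(SeqRecord("r", raw)).seq
    assert set(once) <= set("ACGTN")
    assert sanitize_record(SeqRecord("r", once)).seq == once


def test_dedup_keeps_first_of_exact_duplicates():
    recs = [SeqRecord("a", "ACGT"), SeqRecord("b", "ACGT"), SeqRecord("c", "ACGG")]
    stats = DbStats()
    survivors = list(dedup_stream(recs, stats))
    assert [r.id for r in survivors] == ["a", "c"]
    assert stats.n_duplicates_removed == 1
    assert stats.n_bases == 8


def test_dedup_is_idempotent():
    rng = np.random.default_rng(0)
    recs = [
        SeqRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=20)))
        for i in range(50)
    ]
    once = list(dedup_stream(recs))
    twice = list(dedup_stream(once))
    assert [(r.id, r.seq) for r in once] == [(r.id, r.seq) for r in twice]


def test_dedup_survivor_count_with_planted_duplicates():
    """1000 random 50-mers containing 100 planted exact copies -> 900 left."""
    rng = np.random.default_rng(42)
    uniques = []
    while len(uniques) < 900:
        s = "".join(rng.choice(list("ACGT"), size=50))
        if s not in uniques:
            uniques.append(s)
    dup_sources = rng.choice(900, size=100, replace=False)
    seqs = uniques + [uniques[i] for i in dup_sources]
    order = rng.permutation(1000)
    # planted copies must come after their source to keep the keep-first count
    recs = [SeqRecord(f"r{i}", seqs[i]) for i in range(900)]
    recs += [SeqRecord(f"d{i}", seqs[900 + i]) for i in range(100)]
    stats = DbStats()
    survivors = list(dedup_stream(recs, stats))
    assert len(survivors) == 900
    assert stats.n_duplicates_removed == 100
    # brute-force oracle: distinct sequence strings
    assert {r.seq for r in survivors} == set(uniques)


def test_build_database_merges_shared_sequences(tmp_path):
    f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_fasta([SeqRecord("x", "ACGTACGT"), SeqRecord("y", "GGGG")], f1)
    write_fasta([SeqRecord("z", "acgtacgt")], f2)  # same sequence as x after casefold
    out = tmp_path / "db.fa"
    stats = build_database([f1, f2], out)
    recs = list(read_fasta(out))
    assert [r.id for r in recs] == ["x", "y"]
    assert stats.n_sequences == 2
    assert stats.n_duplicates_removed == 1


def test_build_database_empty_inputs(tmp_path):
    out = tmp_path / "db.fa"
    stats = build_database([], out)
    assert stats == DbStats()
    assert list(read_fasta(out)) == []


def test_build_database_stats_match_brute_force(tmp_path):
    rng = np.random.default_rng(5)
    all_seqs = []
    paths = []
    for f in range(3):
        path = tmp_path / f"in{f}.fa"
        recs = []
        for i in range(40):
            s = "".join(rng.choice(list("ACGTU-ryn"), size=int(rng.integers(10, 40))))
            recs.append(SeqRecord(f"f{f}_r{i}", s))
            all_seqs.append(s)
        write_fasta(recs, path)
        paths.append(path)
    out = tmp_path / "db.fa"
    stats = build_database(paths, out)
    # independent one-pass oracle: sanitize then set over sequence strings
    sanitized = [seqdb.sanitize_seq(s) for s in all_seqs]
    distinct = list(dict.fromkeys(sanitized))
    assert stats.n_sequences == len(distinct)
    assert stats.n_bases == sum(len(s) for s in distinct)
    assert stats.n_duplicates_removed == len(sanitized) - len(distinct)


def _mk_db(tmp_path, n=30, seed=1):
    rng = np.random.default_rng(seed)
    recs = [
        SeqRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 120)))))
        for i in range(n)
    ]
    db = tmp_path / "db.fa"
    write_fasta(recs, db)
    return db, recs


def test_split_volumes_round_trip(tmp_path):
    """Concatenating all volumes reproduces the database record sequence."""
    db, recs = _mk_db(tmp_path)
    manifest = split_volumes(db, tmp_path / "vols", volume_size_bytes=400)
    assert len(manifest.volume_paths) > 1
    rejoined = [r for p in manifest.volume_paths for r in read_fasta(p)]
    assert [(r.id, r.seq) for r in rejoined] == [(r.id, r.seq) for r in recs]
    assert sum(manifest.volume_record_counts) == len(recs)
    assert manifest.total_residues == sum(len(r.seq) for r in recs)


def test_split_volumes_greedy_packing(tmp_path):
    """Records that fit go in the current volume; each volume obeys the cap
    unless a single record exceeds it."""
    db, recs = _mk_db(tmp_path, n=20, seed=2)
    sizes = [len(seqdb.format_fasta_record(r).encode()) for r in recs]
    cap = 3 * max(sizes)
    manifest = split_volumes(db, tmp_path / "vols", volume_size_bytes=cap)
    assert all(b <= cap for b in manifest.volume_byte_sizes)


def test_split_oversized_record_gets_own_volume(tmp_path, caplog):
    db = tmp_path / "db.fa"
    write_fasta([SeqRecord("big", "A" * 500), SeqRecord("small", "ACGT")], db)
    with caplog.at_level("WARNING", logger="rnahomkit.seqdb"):
        manifest = split_volumes(db, tmp_path / "vols", volume_size_bytes=100)
    assert manifest.volume_record_counts == [1, 1]
    assert manifest.volume_byte_sizes[0] > 100
    assert any("exceeds volume size" in r.message for r in caplog.records)


def test_manifest_round_trip(tmp_path):
    db, _ = _mk_db(tmp_path)
    manifest = split_volumes(db, tmp_path / "vols", volume_size_bytes=500)
    path = tmp_path / "manifest.tsv"
    manifest.write(path)
    loaded = seqdb.VolumeManifest.read(path)
    assert loaded == manifest
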