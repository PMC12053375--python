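"""Nucleotide sequence database construction, sanitization, and volume splitting.

A searchable database is built from one or more FASTA files by concatenating
them in order, normalizing every record to the DNA alphabet ``{A,C,G,T,N}``,
dropping chromosome-scale records above a length cap, removing 100%-identical
duplicate sequences (keep-first), and finally splitting the resulting single
FASTA into fixed-size volumes so that searches can run per volume and be
merged afterwards.  The volume manifest records the residue total ``Z`` of the
*whole* database, which downstream E-value normalization requires.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("rnahomkit.seqdb")

# Sanitization: uppercase, U->T, everything outside ACGT -> N.
def _build_sanitize_table() -> bytes:
    table = bytearray(b"N" * 256)
    for ch in "ACGT":
        table[ord(ch)] = table[ord(ch.lower())] = ord(ch)
    table[ord("U")] = table[ord("u")] = ord("T")
    return bytes(table)


_SANITIZE = _build_sanitize_table()

#: default length cap, in bases ("1000 Mb": chromosome-scale records are dropped)
DEFAULT_MAX_LEN = 10**9

#: desk-scale default volume size in serialized FASTA bytes
DEFAULT_VOLUME_SIZE = 10 * 1024 * 1024

FASTA_WRAP = 60


class InvalidRecordError(ValueError):
    """Raised for records that violate the database contract (e.g. empty)."""


class FastaParseError(ValueError):
    """Raised when an input FASTA cannot be parsed; names file and record index."""


@dataclass
class SeqRecord:
    """One nucleotide sequence; the unit of database construction."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DbStats:
    """Counts accumulated while building a database."""

    n_sequences: int = 0
    n_bases: int = 0
    n_dropped_long: int = 0
    n_duplicates_removed: int = 0


@dataclass
class VolumeManifest:
    """Where each volume lives and how big it is; ``total_residues`` is the
    database-wide residue count Z used for E-value normalization."""

    volume_paths: list[str] = field(default_factory=list)
    volume_record_counts: list[int] = field(default_factory=list)
    volume_byte_sizes: list[int] = field(default_factory=list)
    volume_residue_counts: list[int] = field(default_factory=list)
    total_residues: int = 0

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_residues\t{self.total_residues}\n")
            fh.write("volume_path\tn_records\tn_bytes\tn_residues\n")
            for p, n, b, r in zip(
                self.volume_paths,
                self.volume_record_counts,
                self.volume_byte_sizes,
                self.volume_residue_counts,
            ):
                fh.write(f"{p}\t{n}\t{b}\t{r}\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "VolumeManifest":
        m = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#total_residues"):
                raise FastaParseError(f"{path}: not a volume manifest")
            m.total_residues = int(header.split("\t")[1])
            fh.readline()  # column header
            for line in fh:
                if not line.strip():
                    continue
                p, n, b, r = line.rstrip("\n").split("\t")
                m.volume_paths.append(p)
                m.volume_record_counts.append(int(n))
                m.volume_byte_sizes.append(int(b))
                m.volume_residue_counts.append(int(r))
        return m


# ---------------------------------------------------------------------------
# sanitization
# ---------------------------------------------------------------------------

#: sentinel returned by :func:`sanitize_record` for records above the length cap
DROP = object()


def sanitize_seq(seq: str) -> str:
    """Uppercase, map U->T and every non-ACGT character (gaps, dashes, IUPAC
    ambiguity codes) to N."""
    return seq.encode("ascii", errors="replace").translate(_SANITIZE).decode("ascii")


def sanitize_record(rec: SeqRecord, max_len: int = DEFAULT_MAX_LEN):
    """Normalize one record to the DNA alphabet, or DROP it if too long.

    Returns the sanitized :class:`SeqRecord`, or the module-level :data:`DROP`
    sentinel for records longer than ``max_len`` bases (length is measured
    before substitution).  Empty sequences are invalid.
    """
    if len(rec.seq) == 0:
        raise InvalidRecordError(f"record {rec.id!r}: empty sequence")
    if len(rec.seq) > max_len:
        return DROP
    return SeqRecord(id=rec.id, seq=sanitize_seq(rec.seq), description=rec.description)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


class _ExactDedupIndex:
    """Membership index over full-length sequence strings.

    Keyed by a 128-bit blake2b digest; the survivor sequence is stored so a
    digest hit is confirmed by byte comparison (correctness over speed).
    """

    def __init__(self) -> None:
        self._by_digest: dict[bytes, list[str]] = {}

    def seen(self, seq: str) -> bool:
        """Return True if ``seq`` was added before; otherwise add it."""
        digest = hashlib.blake2b(seq.encode("ascii"), digest_size=16).digest()
        bucket = self._by_digest.get(digest)
        if bucket is None:
            self._by_digest[digest] = [seq]
            return False
        if seq in bucket:
            return True
        bucket.append(seq)
        return False


def dedup_stream(
    records: Iterable[SeqRecord], stats: DbStats | None = None
) -> Iterator[SeqRecord]:
    """Emit the first occurrence of each distinct sequence string.

    Duplicate detection is exact and full-length on sanitized sequences;
    record identifiers play no role.  Survivor order is input order.  If
    ``stats`` is given, ``n_duplicates_removed``, ``n_sequences`` and
    ``n_bases`` are accumulated on it.
    """
    index = _ExactDedupIndex()
    for rec in records:
        if index.seen(rec.seq):
            if stats is not None:
                stats.n_duplicates_removed += 1
            continue
        if stats is not None:
            stats.n_sequences += 1
            stats.n_bases += len(rec.seq)
        yield rec


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file (any line wrapping)."""
    path = Path(path)
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = str(rec.seq)
            if not seq:
                raise FastaParseError(f"{path}: record {i} ({rec.id!r}) is empty")
            yield SeqRecord(id=rec.id, seq=seq, description=rec.description)
    except FastaParseError:
        raise
    except Exception as exc:  # garbled input
        raise FastaParseError(f"{path}: cannot parse FASTA: {exc}") from exc


def format_fasta_record(rec: SeqRecord, wrap: int = FASTA_WRAP) -> str:
    header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
    body = "\n".join(rec.seq[i : i + wrap] for i in range(0, len(rec.seq), wrap))
    return f"{header}\n{body}\n"


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> int:
    """Write records wrapped at 60 columns; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_fasta_record(rec))
            n += 1
    return n


# ---------------------------------------------------------------------------
# database build + volume split
# ---------------------------------------------------------------------------


def build_database(
    inputs: list[str | os.PathLike],
    out: str | os.PathLike,
    max_len: int = DEFAULT_MAX_LEN,
) -> DbStats:
    """Concatenate input FASTAs in order, sanitize, dedup, write one FASTA."""
    stats = DbStats()

    def pipeline() -> Iterator[SeqRecord]:
        for path in inputs:
            for rec in read_fasta(path):
                cleaned = sanitize_record(rec, max_len=max_len)
                if cleaned is DROP:
                    stats.n_dropped_long += 1
                    continue
                yield cleaned

    write_fasta(dedup_stream(pipeline(), stats), out)
    return stats


def split_volumes(
    db: str | os.PathLike,
    out_dir: str | os.PathLike,
    volume_size_bytes: int = DEFAULT_VOLUME_SIZE,
) -> VolumeManifest:
    """Greedily pack records into volumes of at most ``volume_size_bytes``
    serialized FASTA bytes each.

    A record never spans two volumes; a volume exceeds the size cap only when
    a single record does (logged as a warning).  Concatenating the volumes in
    manifest order reproduces the database record-for-record.
    """
    if volume_size_bytes <= 0:
        raise ValueError("volume_size_bytes must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = VolumeManifest()

    vol_idx = 0
    cur_bytes = cur_records = cur_residues = 0
    fh = None

    def open_volume():
        nonlocal fh, cur_bytes, cur_records, cur_residues, vol_idx
        vol_idx += 1
        path = out_dir / f"volume_{vol_idx:04d}.fa"
        fh = open(path, "w")
        cur_bytes = cur_records = cur_residues = 0
        manifest.volume_paths.append(str(path))

    def close_volume():
        nonlocal fh
        if fh is not None:
            fh.close()
            fh = None
            manifest.volume_record_counts.append(cur_records)
            manifest.volume_byte_sizes.append(cur_bytes)
            manifest.volume_residue_counts.append(cur_residues)

    open_volume()
    for rec in read_fasta(db):
        chunk = format_fasta_record(rec)
        size = len(chunk.encode("ascii"))
        if cur_records > 0 and cur_bytes + size > volume_size_bytes:
            close_volume()
            open_volume()
        if size > volume_size_bytes:
            logger.warning(
                "record %s (%d bytes) exceeds volume size %d; volume oversized",
                rec.id, size, volume_size_bytes,
            )
        fh.write(chunk)
        cur_bytes += size
        cur_records += 1
        cur_residues += len(rec.seq)
    close_volume()

    manifest.total_residues = sum(manifest.volume_residue_counts)
    return manifest
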