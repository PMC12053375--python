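"""Multiple sequence alignment model: I/O, match columns, N_eff, merging.

Alignments here are query-anchored: a designated subset of columns (the
*match columns*, given by the Stockholm ``#=GC RF`` line) define the model /
query coordinate system, while remaining columns are insert states relative
to it.  Uppercase residues and ``-`` live in match columns; lowercase
residues and ``.`` live in insert columns.

Two quantities defined here drive the whole pipeline: pairwise identity over
match columns, and the effective sequence number

    N_eff = sum_i 1 / |{ j : identity(i, j) >= t }|     (t = 0.8 by default)

which is both the depth gate for iterating the homology search and the
sequence-reweighting scheme used by the coupling analysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

GAP_CHARS = frozenset("-.")

#: default identity threshold for clustering/reweighting
DEFAULT_IDENTITY_THRESHOLD = 0.8

#: N_eff depth categories (lower-inclusive bin edges)
NEFF_BINS = (("no-hit", 0.0), ("low", 1.0), ("medium", 10.0), ("high", 50.0))


class MsaFormatError(ValueError):
    """Malformed alignment file (ragged rows, missing reference line, ...)."""


class IncompatibleModelError(ValueError):
    """Alignments built from different models cannot be merged."""


@dataclass
class Msa:
    """An alignment with per-column match/insert annotation.

    ``rows[i]`` is the aligned string for ``names[i]``; all rows share one
    length.  ``match_columns`` is a boolean mask over columns.  ``query_index``
    marks the query row when present (row 0 throughout the pipeline).
    """

    names: list[str]
    rows: list[str]
    match_columns: np.ndarray  # bool, per column
    query_index: int | None = None
    ss_cons: str | None = None  # optional consensus structure annotation

    def __post_init__(self) -> None:
        self.match_columns = np.asarray(self.match_columns, dtype=bool)
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise MsaFormatError(f"ragged rows: widths {sorted(widths)}")
        if self.rows and len(self.rows[0]) != self.match_columns.size:
            raise MsaFormatError("match_columns length does not match row width")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return int(self.match_columns.size)

    @property
    def n_match_columns(self) -> int:
        return int(self.match_columns.sum())

    def match_only_rows(self) -> list[str]:
        """Rows restricted to match columns, uppercased, '.' -> '-'."""
        idx = np.flatnonzero(self.match_columns)
        out = []
        for row in self.rows:
            out.append(
                "".join("-" if row[i] in GAP_CHARS else row[i].upper() for i in idx)
            )
        return out

    def ungapped(self, i: int) -> str:
        """Residues of row ``i`` with all gap characters removed, uppercased."""
        return "".join(c.upper() for c in self.rows[i] if c not in GAP_CHARS)

    def take_rows(self, indices: Sequence[int]) -> "Msa":
        indices = list(indices)
        qi = None
        if self.query_index is not None and self.query_index in indices:
            qi = indices.index(self.query_index)
        return Msa(
            names=[self.names[i] for i in indices],
            rows=[self.rows[i] for i in indices],
            match_columns=self.match_columns.copy(),
            query_index=qi,
            ss_cons=self.ss_cons,
        )


def query_only_msa(name: str, seq: str) -> Msa:
    """The degenerate one-row alignment holding just the query."""
    return Msa(
        names=[name],
        rows=[seq.upper().replace("T", "U")],
        match_columns=np.ones(len(seq), dtype=bool),
        query_index=0,
    )


# ---------------------------------------------------------------------------
# I/O: Stockholm 1.0 (with #=GC RF) and aligned FASTA
# ---------------------------------------------------------------------------


def _rf_to_mask(rf: str) -> np.ndarray:
    # gap characters in RF mark insert columns; anything else is a match column
    return np.array([c not in GAP_CHARS and c != "~" for c in rf], dtype=bool)


def _mask_to_rf(mask: np.ndarray) -> str:
    return "".join("x" if m else "." for m in mask)


def read_msa(path: str | os.PathLike, format: str = "stockholm") -> Msa:
    """Read an alignment; for Stockholm the ``#=GC RF`` line defines match
    columns, for aligned FASTA every column is a match column."""
    if format == "afa":
        aln = AlignIO.read(str(path), "fasta")
        names = [r.id for r in aln]
        rows = [str(r.seq) for r in aln]
        return Msa(names, rows, np.ones(aln.get_alignment_length(), dtype=bool))
    if format != "stockholm":
        raise ValueError(f"unknown MSA format {format!r}")
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise MsaFormatError(f"{path}: {exc}") from exc
    rf = aln.column_annotations.get("reference_annotation")
    if rf is None:
        raise MsaFormatError(f"{path}: Stockholm file lacks a #=GC RF reference line")
    ss = aln.column_annotations.get("secondary_structure")
    return Msa(
        names=[r.id for r in aln],
        rows=[str(r.seq) for r in aln],
        match_columns=_rf_to_mask(rf),
        ss_cons=ss,
    )


def write_msa(msa: Msa, path: str | os.PathLike, format: str = "stockholm") -> None:
    if format == "afa":
        with open(path, "w") as fh:
            for name, row in zip(msa.names, msa.rows):
                fh.write(f">{name}\n{row}\n")
        return
    if format != "stockholm":
        raise ValueError(f"unknown MSA format {format!r}")
    records = [
        BioSeqRecord(Seq(row), id=name, description="")
        for name, row in zip(msa.names, msa.rows)
    ]
    aln = MultipleSeqAlignment(records)
    aln.column_annotations["reference_annotation"] = _mask_to_rf(msa.match_columns)
    if msa.ss_cons is not None:
        aln.column_annotations["secondary_structure"] = msa.ss_cons
    buf = StringIO()
    AlignIO.write(aln, buf, "stockholm")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# identity, weights, N_eff
# ---------------------------------------------------------------------------


def pairwise_identity(row_a: str, row_b: str, match_columns: np.ndarray) -> float:
    """Fraction of match columns with identical non-gap residues, out of match
    columns where at least one row is non-gap; 0 if that denominator is 0."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    idx = np.flatnonzero(np.asarray(match_columns, dtype=bool))
    same = either = 0
    for i in idx:
        a, b = row_a[i], row_b[i]
        ga, gb = a in GAP_CHARS, b in GAP_CHARS
        if ga and gb:
            continue
        either += 1
        if not ga and not gb and a.upper() == b.upper():
            same += 1
    return same / either if either else 0.0


def _encode_match(msa: Msa) -> np.ndarray:
    """uint8 matrix over match columns; 0 encodes gap."""
    rows = msa.match_only_rows()
    codes = np.zeros((len(rows), msa.n_match_columns), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.uint8)
    for k, ch in enumerate("ACGUTN", start=1):
        lut[ord(ch)] = k
    for i, row in enumerate(rows):
        codes[i] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    return codes


def identity_matrix(msa: Msa) -> np.ndarray:
    """All-vs-all pairwise identity over match columns (vectorized)."""
    codes = _encode_match(msa)
    n = codes.shape[0]
    ident = np.ones((n, n))
    if n == 0 or codes.shape[1] == 0:
        return ident
    nongap = codes != 0
    # chunk rows to bound the broadcast at ~n*chunk*L bytes
    chunk = max(1, int(2e7 // max(1, n * codes.shape[1])))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        both = nongap[s:e, None, :] & nongap[None, :, :]
        same = ((codes[s:e, None, :] == codes[None, :, :]) & both).sum(axis=2)
        either = (nongap[s:e, None, :] | nongap[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident[s:e] = np.where(either > 0, same / np.maximum(either, 1), 0.0)
    return ident


def sequence_weights(
    msa: Msa, threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> np.ndarray:
    """w_i = 1 / (number of rows at identity >= threshold to row i, self included)."""
    if msa.n_rows == 0:
        return np.zeros(0)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ident = identity_matrix(msa)
    counts = (ident >= threshold).sum(axis=1)
    return 1.0 / counts


@dataclass
class NeffReport:
    neff: float
    n_rows: int
    identity_threshold: float
    category: str


def neff_category(neff: float) -> str:
    # bins: 0 -> no-hit; [1,10) low; [10,50) medium; >=50 high
    if neff >= 50:
        return "high"
    if neff >= 10:
        return "medium"
    if neff >= 1:
        return "low"
    return "no-hit"


def neff(msa: Msa, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> NeffReport:
    """Effective sequence number: the sum of sequence weights.

    An empty alignment reports N_eff = 0 ("no-hit"); any non-empty alignment
    has 1 <= N_eff <= n_rows.
    """
    if msa.n_rows == 0:
        return NeffReport(0.0, 0, threshold, "no-hit")
    value = float(sequence_weights(msa, threshold).sum())
    # mathematically 1 <= N_eff <= n_rows; guard against float round-off
    value = min(max(value, 1.0), float(msa.n_rows))
    return NeffReport(value, msa.n_rows, threshold, neff_category(value))


# ---------------------------------------------------------------------------
# merging per-volume alignments
# ---------------------------------------------------------------------------


def _insert_slots(msa: Msa) -> list[list[int]]:
    """Column indices of insert columns grouped by the match column they
    follow; slot 0 holds inserts before the first match column."""
    slots: list[list[int]] = [[] for _ in range(msa.n_match_columns + 1)]
    k = 0
    for j in range(msa.n_columns):
        if msa.match_columns[j]:
            k += 1
        else:
            slots[k].append(j)
    return slots


def merge_alignments(parts: Sequence[Msa]) -> Msa:
    """Merge per-volume alignments that share one model.

    Match columns align one-to-one across parts.  Each part's insert columns
    are kept as distinct columns attached after their anchoring match column
    (part order), padded with ``.`` in rows from other parts.  Row order is
    the concatenation of part row orders.
    """
    parts = [p for p in parts]
    if not parts:
        raise ValueError("no alignments to merge")
    m = parts[0].n_match_columns
    for p in parts:
        if p.n_match_columns != m:
            raise IncompatibleModelError(
                f"match-column counts differ: {m} vs {p.n_match_columns}"
            )
    part_slots = [_insert_slots(p) for p in parts]
    part_match = [np.flatnonzero(p.match_columns) for p in parts]

    # merged column plan: per slot k, each part's insert block, then match col k+1
    names: list[str] = []
    rows: list[str] = []
    mask: list[bool] = []
    plan: list[tuple[str, int, int | list[int]]] = []  # (kind, part, cols)
    for k in range(m + 1):
        for pi, slots in enumerate(part_slots):
            for col in slots[k]:
                plan.append(("insert", pi, col))
                mask.append(False)
        if k < m:
            plan.append(("match", -1, k))
            mask.append(True)

    query_index = None
    for pi, part in enumerate(parts):
        for ri, row in enumerate(part.rows):
            chars = []
            for kind, owner, col in plan:
                if kind == "match":
                    chars.append(row[part_match[pi][col]])
                elif owner == pi:
                    chars.append(row[col])
                else:
                    chars.append(".")
            if part.query_index == ri and query_index is None:
                query_index = len(rows)
            names.append(part.names[ri])
            rows.append("".join(chars))

    ss = next((p.ss_cons for p in parts if p.ss_cons is not None), None)
    if ss is not None:
        # project the first annotated part's structure onto merged columns
        src = next(p for p in parts if p.ss_cons is not None)
        ss_match = [src.ss_cons[i] for i in np.flatnonzero(src.match_columns)]
        out = []
        mi = 0
        for is_match in mask:
            out.append(ss_match[mi] if is_match else ".")
            mi += is_match
        ss = "".join(out)

    return Msa(names, rows, np.array(mask, dtype=bool), query_index, ss)


def dedup_rows(msa: Msa) -> Msa:
    """Drop non-query rows whose full aligned string duplicates an earlier
    non-query row; the query row is always kept and never shadows a hit."""
    seen: set[str] = set()
    keep: list[int] = []
    for i, row in enumerate(msa.rows):
        if i == msa.query_index:
            keep.append(i)
            continue
        if row not in seen:
            seen.add(row)
            keep.append(i)
    return msa.take_rows(keep)
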