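"""Synthetic RNA families with planted secondary structure and covariation.

Families are evolved from a random ancestor under a planted nested secondary
structure: paired positions hold canonical base pairs, and when a paired
site substitutes, the partner co-substitutes with probability
``compensatory_prob`` so the pair stays canonical.  These compensatory
events are exactly the covariation signal a coupling analysis must recover,
which makes the generated families ground-truthed end-to-end test inputs
for the whole search-and-score pipeline.  Family members can be embedded in
random flanks among unrelated decoy records to form a toy database with a
volume manifest.

Evolution is a star phylogeny (every member mutates independently from the
ancestor); indels are restricted to loop regions so that structure
coordinates stay aligned across members.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqdb
from .evalbp import PairSet, pairs_to_dotbracket
from .msa import Msa

RNA_BASES = "ACGU"

#: canonical pair vocabulary with GC-biased draw frequencies (GC+CG = 0.5)
CANONICAL_PAIRS = ["GC", "CG", "AU", "UA", "GU", "UG"]
CANONICAL_FREQS = [0.25, 0.25, 0.175, 0.175, 0.075, 0.075]

_PARTNERS = {"A": ["U"], "U": ["A", "G"], "G": ["C", "U"], "C": ["G"]}


@dataclass
class FamilySpec:
    """Parameters of one synthetic family."""

    length: int
    n_members: int
    structure: PairSet | None = None  # sampled from seed when omitted
    sub_rate: float = 0.15
    compensatory_prob: float = 0.97
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.sub_rate, self.compensatory_prob, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates/probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# structure sampling
# ---------------------------------------------------------------------------


def sample_structure(L: int, seed: int) -> PairSet:
    """A random nested structure with minimum loop 3 and at least L/6 pairs.

    Recursive stem-loop placement: an interval either splits into two
    adjacent units or grows an outer stem and recurses inside; intervals too
    short for a stem-loop stay unpaired.  Deterministic per seed.
    """
    if L < 8:
        raise ValueError("structure sampling requires L >= 8")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    stack = [(0, L - 1)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo + 1
        if n < 8:
            continue
        if n >= 20 and rng.random() < 0.35:
            cut = int(rng.integers(lo + 7, hi - 7))
            stack.append((cut + 1, hi))
            stack.append((lo, cut))
            continue
        smax = (n - 3) // 2
        s = int(rng.integers(2, min(smax, 8) + 1))
        for k in range(s):
            pairs.append((lo + k + 1, hi - k + 1))  # 1-based
        stack.append((lo + s, hi - s))

    return PairSet(frozenset(pairs), L)


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------


def _draw_pair(rng: np.random.Generator) -> str:
    return CANONICAL_PAIRS[rng.choice(len(CANONICAL_PAIRS), p=CANONICAL_FREQS)]


def sample_ancestor(structure: PairSet, rng: np.random.Generator) -> str:
    """Random ancestor respecting the structure: canonical residues at paired
    positions, uniform elsewhere."""
    seq = [RNA_BASES[rng.integers(0, 4)] for _ in range(structure.length)]
    for i, j in sorted(structure.pairs):
        pair = _draw_pair(rng)
        seq[i - 1], seq[j - 1] = pair[0], pair[1]
    return "".join(seq)


def _mutate_member(
    ancestor: str, structure: PairSet, spec: FamilySpec, rng: np.random.Generator
) -> list[str]:
    """One member as a per-ancestor-position list; deletions become '',
    insertions are appended (lowercase) to the preceding position's cell."""
    cells = list(ancestor)
    paired_at = {}
    for i, j in structure.pairs:
        paired_at[i - 1] = j - 1
        paired_at[j - 1] = i - 1
    done = set()
    for pos in range(len(ancestor)):
        if pos in done:
            continue
        partner = paired_at.get(pos)
        if partner is None:
            if rng.random() < spec.sub_rate:
                alts = [b for b in RNA_BASES if b != cells[pos]]
                cells[pos] = alts[rng.integers(0, 3)]
        else:
            done.add(partner)
            if rng.random() < spec.sub_rate:
                old = cells[pos]
                alts = [b for b in RNA_BASES if b != old]
                new = alts[rng.integers(0, 3)]
                cells[pos] = new
                if rng.random() < spec.compensatory_prob:
                    partners = _PARTNERS[new]
                    cells[partner] = partners[rng.integers(0, len(partners))]
    # indels only in loops (unpaired positions), never at structure sites
    if spec.indel_rate > 0:
        out: list[str] = []
        for pos, cell in enumerate(cells):
            if pos in paired_at:
                out.append(cell)
                continue
            r = rng.random()
            if r < spec.indel_rate / 2:
                out.append("")  # deletion
            elif r < spec.indel_rate:
                out.append(cell + RNA_BASES[rng.integers(0, 4)].lower())
            else:
                out.append(cell)
        cells = out
    return cells


def evolve_family(spec: FamilySpec) -> tuple[list[str], PairSet, str]:
    """Evolve ``n_members`` sequences; returns (members, structure, ancestor)."""
    rng = np.random.default_rng(spec.seed)
    structure = spec.structure or sample_structure(spec.length, spec.seed)
    ancestor = sample_ancestor(structure, rng)
    members = []
    for _ in range(spec.n_members):
        cells = _mutate_member(ancestor, structure, spec, rng)
        members.append("".join(cells).upper())
    return members, structure, ancestor


def family_msa(spec: FamilySpec, query_first: bool = True) -> tuple[Msa, PairSet]:
    """Family as a ready-made alignment on ancestor coordinates.

    Match columns are the ancestor positions; loop insertions become insert
    columns and loop deletions gaps.  Row 0 is the first member, designated
    as the query when ``query_first``.
    """
    rng = np.random.default_rng(spec.seed)
    structure = spec.structure or sample_structure(spec.length, spec.seed)
    ancestor = sample_ancestor(structure, rng)
    all_cells = [
        _mutate_member(ancestor, structure, spec, rng)
        for _ in range(spec.n_members)
    ]
    width = [
        max(max(len(c[pos]), 1) for c in all_cells)
        for pos in range(spec.length)
    ]
    rows = []
    mask: list[bool] = []
    for pos in range(spec.length):
        mask.append(True)
        mask.extend([False] * (width[pos] - 1))
    for cells in all_cells:
        chars: list[str] = []
        for pos in range(spec.length):
            cell = cells[pos]
            match = cell[:1] if cell else "-"
            ins = cell[1:]
            chars.append(match.upper() if match != "-" else "-")
            chars.append(ins.lower().ljust(width[pos] - 1, "."))
        rows.append("".join(chars))
    names = [f"member_{k}" for k in range(spec.n_members)]
    msa = Msa(names, rows, np.array(mask, dtype=bool),
              query_index=0 if query_first else None)
    return msa, structure


# ---------------------------------------------------------------------------
# toy databases
# ---------------------------------------------------------------------------


def random_decoy(
    length: int,
    rng: np.random.Generator,
    exclude_kmers: set[str] | None = None,
    k: int = 11,
    max_tries: int = 200,
) -> str:
    """Uniform random DNA decoy; with ``exclude_kmers`` the decoy is resampled
    until it shares no k-mer (either strand) with the excluded set."""
    from .pipeline import revcomp

    for _ in range(max_tries):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        if exclude_kmers is None:
            return seq
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        rc = revcomp(seq)
        kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
        if not (kmers & exclude_kmers):
            return seq
    raise RuntimeError("could not generate a k-mer-free decoy; relax the filter")


@dataclass
class ToyDb:
    db_path: str
    manifest: seqdb.VolumeManifest
    manifest_path: str
    member_ids: list[list[str]]  # per family
    structures: list[PairSet]
    queries: list[tuple[str, str]]  # (name, RNA seq): member 0 of each family


def _volume_size_for(db_path: str, n_volumes: int) -> int:
    """Smallest volume size that greedy packing turns into exactly
    ``n_volumes`` volumes (binary search; packing count is monotone)."""
    sizes = [
        len(seqdb.format_fasta_record(rec).encode("ascii"))
        for rec in seqdb.read_fasta(db_path)
    ]
    total = sum(sizes)
    if n_volumes <= 1:
        return total

    def count(vsize: int) -> int:
        nvol, cur, nrec = 1, 0, 0
        for s in sizes:
            if nrec > 0 and cur + s > vsize:
                nvol += 1
                cur = nrec = 0
            cur += s
            nrec += 1
        return nvol

    lo, hi = max(sizes), total
    while lo < hi:
        mid = (lo + hi) // 2
        if count(mid) <= n_volumes:
            hi = mid
        else:
            lo = mid + 1
    if count(lo) != n_volumes:
        raise ValueError(f"cannot split into exactly {n_volumes} volumes")
    return lo


def make_toy_db(
    families: list[FamilySpec],
    n_decoys: int,
    out_dir: str | os.PathLike,
    decoy_len_range: tuple[int, int] = (100, 300),
    flank_len_range: tuple[int, int] = (20, 60),
    n_volumes: int = 2,
    seed: int = 0,
    exclude_query_kmers: bool = True,
) -> ToyDb:
    """Build a FASTA database of family members embedded in random flanks
    plus unrelated decoys, shuffled and split into volumes.

    With ``exclude_query_kmers`` decoys (and flanks) are filtered to share no
    11-mer with any family query, so seed searches cannot hit them by
    construction.  Truth files (structure dot-bracket, member TSV) are
    written next to the database.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    member_ids: list[list[str]] = []
    structures: list[PairSet] = []
    queries: list[tuple[str, str]] = []
    records: list[seqdb.SeqRecord] = []

    exclude: set[str] = set()
    fams = []
    for fi, spec in enumerate(families):
        members, structure, _ = evolve_family(spec)
        fams.append(members)
        structures.append(structure)
        queries.append((f"fam{fi}_query", members[0]))
        if exclude_query_kmers:
            from .pipeline import revcomp

            q = members[0].replace("U", "T")
            for s in (q, revcomp(q)):
                exclude |= {s[i : i + 11] for i in range(len(s) - 10)}

    kw = exclude if exclude_query_kmers else None
    for fi, members in enumerate(fams):
        ids = []
        for mi, member in enumerate(members):
            lf = random_decoy(int(rng.integers(*flank_len_range)), rng, kw)
            rf = random_decoy(int(rng.integers(*flank_len_range)), rng, kw)
            rid = f"fam{fi}_m{mi}"
            ids.append(rid)
            records.append(
                seqdb.SeqRecord(rid, lf + member.replace("U", "T") + rf)
            )
        member_ids.append(ids)

    for d in range(n_decoys):
        records.append(
            seqdb.SeqRecord(
                f"decoy_{d}",
                random_decoy(int(rng.integers(*decoy_len_range)), rng, kw),
            )
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    raw = out_dir / "raw.fa"
    seqdb.write_fasta(records, raw)
    db_path = out_dir / "db.fa"
    seqdb.build_database([str(raw)], db_path)

    vsize = _volume_size_for(str(db_path), n_volumes)
    manifest = seqdb.split_volumes(db_path, out_dir / "volumes", vsize)
    manifest_path = out_dir / "manifest.tsv"
    manifest.write(manifest_path)

    for fi, structure in enumerate(structures):
        with open(out_dir / f"fam{fi}_structure.db", "w") as fh:
            fh.write(pairs_to_dotbracket(structure) + "\n")
    with open(out_dir / "members.tsv", "w") as fh:
        fh.write("family\tmember_id\n")
        for fi, ids in enumerate(member_ids):
            for rid in ids:
                fh.write(f"{fi}\t{rid}\n")

    return ToyDb(
        db_path=str(db_path),
        manifest=manifest,
        manifest_path=str(manifest_path),
        member_ids=member_ids,
        structures=structures,
        queries=queries,
    )
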