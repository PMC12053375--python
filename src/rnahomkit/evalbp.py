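"""Reference secondary structures and base-pair scoring.

Predicted pairs are scored against a reference structure with the standard
protocol for coupling-analysis benchmarks: both sets are first restricted to
non-local pairs (|i - j| > 3), then

    SN = TP / (TP + FN),  PR = TP / (TP + FP),  F1 = 2 * PR * SN / (PR + SN)

with a convention of 0 whenever a denominator vanishes.  Per-set summaries
report the arithmetic mean of per-RNA F1/PR/SN and the median N_eff.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

#: pairs with |i - j| <= 3 are local and excluded from scoring
DEFAULT_MIN_SEP = 4

_BRACKET_PAIRS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKET_PAIRS.items()}


class StructureFormatError(ValueError):
    """Malformed structure file; message carries the offending line."""


@dataclass(frozen=True)
class PairSet:
    """Base pairs as a set of 1-based (i, j) with i < j, on a length-L RNA."""

    pairs: frozenset[tuple[int, int]]
    length: int

    def nonlocal_pairs(self, min_sep: int = DEFAULT_MIN_SEP) -> "PairSet":
        return PairSet(
            frozenset((i, j) for i, j in self.pairs if j - i >= min_sep),
            self.length,
        )


@dataclass
class PairEval:
    tp: int
    fp: int
    fn: int
    pr: float
    sn: float
    f1: float


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_dotbracket(text: str) -> PairSet:
    """Dot-bracket with any of the tiers (), [], {}, <>; all tiers contribute
    pairs (pseudoknots included)."""
    structure = text.strip().splitlines()
    # allow an optional FASTA-like header and sequence line before the structure
    line = next(
        (
            ln.strip()
            for ln in structure
            if ln.strip() and not ln.startswith(">")
            and set(ln.strip()) <= set(".()[]{}<>-_,")
        ),
        None,
    )
    if line is None:
        raise StructureFormatError("no dot-bracket line found")
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKET_PAIRS}
    pairs = set()
    for pos, ch in enumerate(line, start=1):
        if ch in _BRACKET_PAIRS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise StructureFormatError(
                    f"unbalanced {ch!r} at position {pos}"
                )
            pairs.add((stacks[opener].pop(), pos))
    for opener, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced {opener!r} at position {stack[-1]}"
            )
    return PairSet(frozenset(pairs), len(line))


def _parse_ct(lines: list[str]) -> PairSet:
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureFormatError("line 1: CT header must start with a count") from exc
    pairs = set()
    for ln_no, line in enumerate(lines[1 : n + 1], start=2):
        fields = line.split()
        if len(fields) < 6:
            raise StructureFormatError(f"line {ln_no}: short CT record")
        idx, partner = int(fields[0]), int(fields[4])
        if idx != ln_no - 1:
            raise StructureFormatError(
                f"line {ln_no}: index {idx} out of order (expected {ln_no - 1})"
            )
        if partner > 0:
            pairs.add((min(idx, partner), max(idx, partner)))
    return PairSet(frozenset(pairs), n)


def _parse_bpseq(lines: list[str]) -> PairSet:
    pairs = set()
    n = 0
    for ln_no, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise StructureFormatError(f"line {ln_no}: BPSEQ needs 3 fields")
        idx, partner = int(fields[0]), int(fields[2])
        n = max(n, idx)
        if partner > 0:
            pairs.add((min(idx, partner), max(idx, partner)))
    return PairSet(frozenset(pairs), n)


def parse_structure(path: str | os.PathLike, format: str | None = None) -> PairSet:
    """Read a reference structure from dot-bracket (.db/.dbn), CT, or BPSEQ.

    The format is inferred from the extension when not given.
    """
    path = str(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".ct": "ct", ".bpseq": "bpseq"}.get(ext, "dotbracket")
    with open(path) as fh:
        text = fh.read()
    if format == "dotbracket":
        return parse_dotbracket(text)
    lines = text.splitlines()
    if format == "ct":
        return _parse_ct(lines)
    if format == "bpseq":
        return _parse_bpseq(lines)
    raise ValueError(f"unknown structure format {format!r}")


def pairs_to_dotbracket(pairs: PairSet) -> str:
    """Nested pairs back to dot-bracket (raises if pairs cross)."""
    out = ["."] * pairs.length
    for i, j in sorted(pairs.pairs):
        out[i - 1] = "("
        out[j - 1] = ")"
    s = "".join(out)
    if parse_dotbracket(s).pairs != pairs.pairs:
        raise ValueError("pair set is not nested; cannot encode in one tier")
    return s


def write_ct(pairs: PairSet, seq: str, path: str | os.PathLike,
             name: str = "structure") -> None:
    partner = [0] * (pairs.length + 1)
    for i, j in pairs.pairs:
        partner[i], partner[j] = j, i
    with open(path, "w") as fh:
        fh.write(f"{pairs.length} {name}\n")
        for i in range(1, pairs.length + 1):
            nxt = i + 1 if i < pairs.length else 0
            fh.write(f"{i} {seq[i - 1]} {i - 1} {nxt} {partner[i]} {i}\n")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def evaluate_pairs(
    pred: PairSet, truth: PairSet, min_sep: int = DEFAULT_MIN_SEP
) -> PairEval:
    """TP/FP/FN and PR/SN/F1 after restricting both sets to non-local pairs."""
    p = pred.nonlocal_pairs(min_sep).pairs
    t = truth.nonlocal_pairs(min_sep).pairs
    tp = len(p & t)
    fp = len(p - t)
    fn = len(t - p)
    pr = tp / (tp + fp) if tp + fp else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pr * sn / (pr + sn) if pr + sn else 0.0
    return PairEval(tp=tp, fp=fp, fn=fn, pr=pr, sn=sn, f1=f1)


def aggregate(
    evals: list[PairEval], neffs: list[float], set_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-set mean F1/PR/SN and median N_eff (one row per set name).

    Means are arithmetic means of per-RNA values, not metrics of pooled
    counts — the two differ whenever per-RNA pair counts differ.
    """
    if len(evals) != len(neffs):
        raise ValueError("evals and neffs must be parallel lists")
    if not evals:
        return pd.DataFrame(
            columns=["set", "n_rna", "mean_f1", "mean_pr", "mean_sn", "median_neff"]
        )
    if set_names is None:
        set_names = ["all"] * len(evals)
    df = pd.DataFrame(
        {
            "set": set_names,
            "f1": [e.f1 for e in evals],
            "pr": [e.pr for e in evals],
            "sn": [e.sn for e in evals],
            "neff": neffs,
        }
    )
    out = (
        df.groupby("set", sort=False)
        .agg(
            n_rna=("f1", "size"),
            mean_f1=("f1", "mean"),
            mean_pr=("pr", "mean"),
            mean_sn=("sn", "mean"),
            median_neff=("neff", "median"),
        )
        .reset_index()
    )
    return out
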