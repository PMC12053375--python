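"""Iterative volume-split homology search with an N_eff depth gate.

The control flow mirrors covariance-model search pipelines: a fast local
seed search builds an initial alignment (MSA-1); a profile model is built
from MSA-1 plus the query's predicted consensus secondary structure,
calibrated against random sequences, and searched independently against
every database volume; the per-volume alignments are merged into MSA-2.  If
MSA-2 is deep enough (N_eff above the gate, 50 by default) it goes straight
to coupling analysis; otherwise the model is rebuilt from MSA-2 and the
volume search repeats once more (MSA-3).

Engines are pluggable: the ``builtin`` engines implement every step
hermetically (k-mer-seeded local alignment, Nussinov folding, a
position-specific-score profile aligner with Gumbel-calibrated E-values);
``external`` adapters shell out to BLAST-N / RNAfold / Infernal when those
tools are available.

E-value contract: per-volume searches are always normalized to the residue
total ``Z`` of the *full* database (from the volume manifest), never to the
volume size — this is what makes searching k volumes and merging exactly
equivalent to searching the unsplit database.
"""

from __future__ import annotations

import logging
import math
import os
import shutil
import subprocess
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

from . import msa as msa_mod
from . import seqdb
from .dca import DcaResult, empty_result, run_mfdca
from .msa import Msa, NeffReport, merge_alignments, neff, query_only_msa, sequence_weights

logger = logging.getLogger("rnahomkit.pipeline")

RNA_BASES = "ACGU"
_NEG = -1.0e30

# Karlin–Altschul-style parameters for the builtin +2/-3 (5,2) seed search
_SEED_LAMBDA = 0.625
_SEED_K = 0.41


class EngineError(RuntimeError):
    """An external engine is unavailable or misbehaved."""


class CalibrationError(RuntimeError):
    pass


class StateError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Knobs of the search pipeline.

    ``neff_gate`` is the MSA-2 depth above which no third iteration runs;
    ``seed_evalue`` / ``include_evalue`` are the seed-search and model-search
    inclusion thresholds; engines select builtin vs external per stage.
    """

    neff_gate: float = 50.0
    seed_evalue: float = 1e-3
    include_evalue: float = 10.0
    identity_threshold: float = 0.8
    seed_engine: str = "builtin"
    css_engine: str = "builtin"
    search_engine: str = "builtin"
    kmer_size: int = 11
    n_null: int = 300
    null_len: int | None = None
    gap_open: float = -4.0
    gap_extend: float = -1.0
    recalibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neff_gate <= 0:
            raise ValueError("neff_gate must be positive")
        if self.seed_evalue <= 0 or self.include_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Hit:
    target_id: str
    target_span: tuple[int, int]  # 1-based inclusive on the database record
    strand: str  # '+' or '-'
    bit_score: float
    e_value: float


@dataclass
class ProfileModel:
    """Position-specific log-odds profile with a secondary-structure string
    and Gumbel score calibration."""

    match_length: int
    emissions: np.ndarray  # (L, 5): A,C,G,U log-odds + non-standard penalty
    gap_open: float
    gap_extend: float
    css: str
    query_seq: str
    query_name: str
    calibration: tuple[float, float] | None = None  # (mu, beta)
    null_len: int = 0


@dataclass
class RunLog:
    stage: str
    wall_time: float
    n_input: int
    n_output: int
    parameters: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    msa: Msa
    neff_report: NeffReport
    dca_result: DcaResult
    iterations: int
    msa1: Msa
    msa2: Msa
    msa3: Msa | None
    logs: list[RunLog]


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode_target(seq: str) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.int8)  # 4 = non-standard (N etc.)
    for k, ch in enumerate("ACGT"):
        lut[ord(ch)] = k
    lut[ord("U")] = 3
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# consensus secondary structure (builtin: Nussinov maximum base pairing)
# ---------------------------------------------------------------------------

CANONICAL = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
MIN_LOOP = 3


def predict_css(query: str, engine: str = "builtin") -> str:
    """Dot-bracket secondary structure of the query.

    The builtin engine maximizes the number of canonical (AU/GC/GU) nested
    pairs with a minimum hairpin loop of 3 (Nussinov recursion); traceback
    ties are resolved toward the 5'-most pairing partner.  The external
    engine shells out to RNAfold.
    """
    query = query.upper().replace("T", "U")
    if any(c not in RNA_BASES for c in query):
        bad = sorted({c for c in query if c not in RNA_BASES})
        raise ValueError(f"query contains non-RNA residues: {bad}")
    if engine == "external":
        return _rnafold_css(query)
    if engine != "builtin":
        raise EngineError(f"unknown CSS engine {engine!r}")

    n = len(query)
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            can[i, j] = (query[i], query[j]) in CANONICAL
    # dp[i][j] = max pairs within query[i..j] inclusive
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can[i, k]:
                    inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = dp[k + 1, j] if k + 1 < j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i, j] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i, j] == (dp[i + 1, j] if i + 1 <= j else 0):
                # prefer pairing i when it also attains the max (5'-most tie rule)
                paired = False
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if can[i, k]:
                        inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
                        right = dp[k + 1, j] if k + 1 < j else 0
                        if 1 + inner + right == dp[i, j]:
                            structure[i], structure[k] = "(", ")"
                            trace(i + 1, k - 1)
                            i = k + 1
                            paired = True
                            break
                if not paired:
                    i += 1
            else:
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if can[i, k]:
                        inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
                        right = dp[k + 1, j] if k + 1 < j else 0
                        if 1 + inner + right == dp[i, j]:
                            structure[i], structure[k] = "(", ")"
                            trace(i + 1, k - 1)
                            i = k + 1
                            break

    if n > MIN_LOOP:
        trace(0, n - 1)
    return "".join(structure)


def _rnafold_css(query: str) -> str:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise EngineError("RNAfold not found on PATH; use the builtin CSS engine")
    proc = subprocess.run(
        [exe, "--noPS"], input=query + "\n", capture_output=True, text=True, check=True
    )
    for line in proc.stdout.splitlines():
        token = line.split()[0] if line.split() else ""
        if token and set(token) <= set("().,"):
            return token.replace(",", ".")
    raise EngineError("could not parse RNAfold output")


# ---------------------------------------------------------------------------
# profile local alignment (shared by seed search and model search)
# ---------------------------------------------------------------------------


def _local_align(
    emis: np.ndarray, codes: np.ndarray, gap_open: float, gap_extend: float
):
    """Affine-gap local alignment of a position-specific profile against an
    encoded target.  Returns (score, ops) with ops a forward list of
    ('M', col, tpos) / ('D', col) / ('I', tpos), or (0.0, []) if nothing
    scores above zero.  Column indices are 0-based, target positions 1-based.
    """
    L = emis.shape[0]
    n = codes.size
    if n == 0 or L == 0:
        return 0.0, []
    M = np.full((L, n + 1), _NEG)
    I = np.full((L, n + 1), _NEG)
    D = np.full((L, n + 1), _NEG)
    steps = gap_extend * np.arange(L)
    for j in range(1, n + 1):
        e = emis[:, codes[j - 1]]
        prev = np.maximum(np.maximum(M[:, j - 1], D[:, j - 1]), I[:, j - 1])
        prev = np.maximum(prev, 0.0)
        Mj = np.empty(L)
        Mj[0] = e[0]
        Mj[1:] = e[1:] + prev[:-1]
        M[:, j] = Mj
        I[:, j] = np.maximum(M[:, j - 1] + gap_open, I[:, j - 1] + gap_extend)
        run = np.maximum.accumulate(Mj - steps)
        D[1:, j] = gap_open + steps[1:] - gap_extend + run[:-1]

    score = float(M.max())
    if score <= 0.0:
        return 0.0, []
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    j = int(j)
    i = int(i)

    ops: list[tuple] = []
    state = "M"
    tol = 1e-9
    while True:
        if state == "M":
            ops.append(("M", i, j))
            rest = M[i, j] - emis[i, codes[j - 1]]
            if i == 0 or rest <= tol:
                break
            pi, pj = i - 1, j - 1
            if abs(M[pi, pj] - rest) <= tol:
                state = "M"
            elif abs(D[pi, pj] - rest) <= tol:
                state = "D"
            else:
                state = "I"
            i, j = pi, pj
        elif state == "D":
            ops.append(("D", i))
            if abs(M[i - 1, j] + gap_open - D[i, j]) <= tol:
                state = "M"
            else:
                state = "D"
            i -= 1
        else:  # I
            ops.append(("I", j))
            if abs(M[i, j - 1] + gap_open - I[i, j]) <= tol:
                state = "M"
            else:
                state = "I"
            j -= 1
    ops.reverse()
    return score, ops


def _ops_to_row(ops: list[tuple], target: str, L: int) -> tuple[str, np.ndarray, tuple[int, int]]:
    """Render alignment ops as one aligned row on model coordinates.

    Returns (row, match_mask, (tstart, tend)); insert residues are lowercase
    columns attached after their left-adjacent match column.
    """
    match_res = ["-"] * L
    inserts: dict[int, list[str]] = {}
    last_col = -1
    tpositions = [j for op in ops for j in ([op[2]] if op[0] == "M" else [op[1]] if op[0] == "I" else [])]
    for op in ops:
        if op[0] == "M":
            _, col, tpos = op
            match_res[col] = target[tpos - 1].upper().replace("T", "U")
            last_col = col
        elif op[0] == "D":
            match_res[op[1]] = "-"
            last_col = op[1]
        else:  # insert after last consumed column
            inserts.setdefault(last_col + 1, []).append(
                target[op[1] - 1].lower().replace("t", "u")
            )
    cols: list[str] = []
    mask: list[bool] = []
    for slot in range(L + 1):
        for ch in inserts.get(slot, []):
            cols.append(ch)
            mask.append(False)
        if slot < L:
            cols.append(match_res[slot])
            mask.append(True)
    span = (min(tpositions), max(tpositions)) if tpositions else (0, 0)
    return "".join(cols), np.array(mask, dtype=bool), span


# ---------------------------------------------------------------------------
# seed search (MSA-1)
# ---------------------------------------------------------------------------


def _query_profile(query: str) -> np.ndarray:
    """+2/-3 match/mismatch profile of the query (BLAST-N-like scoring)."""
    L = len(query)
    emis = np.full((L, 5), -3.0)
    emis[:, 4] = -3.0
    for i, ch in enumerate(query.upper().replace("U", "T")):
        k = "ACGT".find(ch)
        if k >= 0:
            emis[i, k] = 2.0
    return emis


def _kmer_set(seq: str, k: int) -> set[str]:
    s = seq.upper().replace("U", "T")
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def _seed_evalue(score: float, m: int, n_db: int) -> float:
    bits = (_SEED_LAMBDA * score - math.log(_SEED_K)) / math.log(2.0)
    return m * n_db * (2.0 ** (-bits))


def seed_search(
    query_name: str,
    query: str,
    volume_paths: list[str],
    total_residues: int,
    config: PipelineConfig,
) -> Msa:
    """BLAST-like seeded local search building the initial query-anchored
    alignment (MSA-1).

    The builtin engine requires an exact shared ``kmer_size``-mer before
    aligning a record (either strand), then computes an affine-gap local
    alignment with +2/-3, gap open/extend 5/2; hits with E-value at most
    ``seed_evalue`` (normalized to the full database size) become rows.
    Target insertions relative to the query are dropped, so MSA-1 columns
    are exactly the query positions.
    """
    if config.seed_engine == "external":
        raise EngineError(
            "external seed search (blastn) adapter requires a formatted BLAST "
            "database; use the builtin engine"
        )
    if config.seed_engine != "builtin":
        raise EngineError(f"unknown seed engine {config.seed_engine!r}")
    rna_query = query.upper().replace("T", "U")
    L = len(rna_query)
    emis = _query_profile(rna_query)
    qkmers = _kmer_set(rna_query, config.kmer_size)
    names = [query_name]
    rows = [rna_query]
    for vol in volume_paths:
        for rec in seqdb.read_fasta(vol):
            for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
                if not (qkmers & _kmer_set(seq, config.kmer_size)):
                    continue
                score, ops = _local_align(
                    emis, _encode_target(seq), gap_open=-5.0, gap_extend=-2.0
                )
                if not ops:
                    continue
                e_value = _seed_evalue(score, L, max(total_residues, 1))
                if e_value > config.seed_evalue:
                    continue
                match_res = ["-"] * L
                for op in ops:
                    if op[0] == "M":
                        match_res[op[1]] = seq[op[2] - 1].upper().replace("T", "U")
                    elif op[0] == "D":
                        match_res[op[1]] = "-"
                names.append(f"{rec.id}/{strand}")
                rows.append("".join(match_res))
    out = Msa(names, rows, np.ones(L, dtype=bool), query_index=0)
    return msa_mod.dedup_rows(out)


# ---------------------------------------------------------------------------
# model building, calibration, volume search
# ---------------------------------------------------------------------------


def build_model(
    msa1: Msa,
    css: str,
    config: PipelineConfig | None = None,
) -> ProfileModel:
    """Profile model from an alignment plus the query's structure.

    Match columns are the columns where the query holds a residue; emissions
    are identity-weighted log-odds against a uniform background with one
    pseudocount distributed over the four bases.
    """
    config = config or PipelineConfig()
    if msa1.n_rows == 0:
        raise ValueError("cannot build a model from an empty MSA")
    if msa1.query_index is None:
        raise ValueError("model building requires a designated query row")
    rows = msa1.match_only_rows()
    qrow = rows[msa1.query_index]
    keep = [k for k, c in enumerate(qrow) if c != "-"]
    L = len(keep)
    if len(css) != L:
        raise ValueError(
            f"CSS length {len(css)} does not match query length {L}"
        )
    w = sequence_weights(msa1, config.identity_threshold)
    counts = np.zeros((L, 4))
    for r, row in enumerate(rows):
        for out_k, k in enumerate(keep):
            ch = row[k].replace("T", "U")
            a = RNA_BASES.find(ch)
            if a >= 0:
                counts[out_k, a] += w[r]
    probs = (counts + 0.25) / (counts.sum(axis=1, keepdims=True) + 1.0)
    emis = np.empty((L, 5))
    emis[:, :4] = np.log(probs / 0.25)
    emis[:, 4] = -1.0  # non-standard target residue
    query_seq = "".join(qrow[k] for k in keep)
    return ProfileModel(
        match_length=L,
        emissions=emis,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        css=css,
        query_seq=query_seq,
        query_name=msa1.names[msa1.query_index],
    )


def fit_gumbel(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location mu, scale beta) fit to a sample of
    extreme scores."""
    mu, beta = stats.gumbel_r.fit(np.asarray(samples, dtype=float))
    return float(mu), float(beta)


def gumbel_pvalue(score: float, mu: float, beta: float) -> float:
    """P(max-score >= score) under the fitted null."""
    return float(stats.gumbel_r.sf(score, loc=mu, scale=beta))


def calibrate_model(
    model: ProfileModel,
    n_null: int = 300,
    null_len: int | None = None,
    seed: int = 0,
) -> ProfileModel:
    """Fit a Gumbel law to best-hit scores on random sequences.

    ``n_null`` i.i.d. uniform-random ACGT sequences of length ``null_len``
    (default: twice the model length, at least 100) are scored with the
    profile aligner; the per-sequence maxima are fitted by maximum likelihood
    to a Gumbel (mu, beta), stored on the model together with the null
    length used for E-value normalization.
    """
    if n_null < 200:
        raise ValueError("n_null must be at least 200 for a stable fit")
    if null_len is None:
        null_len = max(100, 2 * model.match_length)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_null)
    for t in range(n_null):
        codes = rng.integers(0, 4, size=null_len).astype(np.int8)
        s, _ = _local_align(model.emissions, codes, model.gap_open, model.gap_extend)
        scores[t] = s
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate null score distribution (all equal)")
    mu, beta = fit_gumbel(scores)
    return replace(model, calibration=(mu, beta), null_len=null_len)


def model_evalue(model: ProfileModel, score: float, z_total: int) -> float:
    if model.calibration is None:
        raise StateError("model is not calibrated")
    mu, beta = model.calibration
    z_scale = z_total / max(model.null_len, 1)
    return z_scale * math.exp(-(score - mu) / beta)


def search_volume(
    model: ProfileModel,
    volume: str,
    z_total: int,
    config: PipelineConfig | None = None,
) -> tuple[list[Hit], Msa]:
    """Scan one volume with the calibrated profile; E-values are normalized
    to the full-database residue total ``z_total`` so that per-volume results
    are database-wide comparable (and merging is exact).

    Returns the accepted hits plus a per-volume alignment part on model
    match-column coordinates (no query row; the query is added at merge).
    """
    config = config or PipelineConfig()
    if model.calibration is None:
        raise StateError("search requires a calibrated model")
    hits: list[Hit] = []
    parts: list[Msa] = []
    for rec in seqdb.read_fasta(volume):
        best = None
        for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
            score, ops = _local_align(
                model.emissions, _encode_target(seq), model.gap_open, model.gap_extend
            )
            if not ops:
                continue
            if best is None or score > best[0]:
                best = (score, ops, strand, seq)
        if best is None:
            continue
        score, ops, strand, seq = best
        e_value = model_evalue(model, score, z_total)
        if e_value > config.include_evalue:
            continue
        row, mask, (ts, te) = _ops_to_row(ops, seq, model.match_length)
        if strand == "-":
            n = len(seq)
            ts, te = n - te + 1, n - ts + 1
        hits.append(
            Hit(
                target_id=rec.id,
                target_span=(ts, te),
                strand=strand,
                bit_score=score / math.log(2.0),
                e_value=e_value,
            )
        )
        parts.append(Msa([f"{rec.id}/{strand}"], [row], mask))
    if parts:
        part = merge_alignments(parts)
    else:
        part = Msa([], [], np.ones(model.match_length, dtype=bool))
    return hits, part


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _project_css(css: str, mask_len: int) -> str:
    return css  # model match columns == query coordinates throughout


def _search_all_volumes(
    model: ProfileModel,
    manifest: seqdb.VolumeManifest,
    config: PipelineConfig,
) -> tuple[list[Hit], Msa]:
    query_part = Msa(
        [model.query_name],
        [model.query_seq],
        np.ones(model.match_length, dtype=bool),
        query_index=0,
        ss_cons=model.css,
    )
    parts = [query_part]
    all_hits: list[Hit] = []
    for vol in manifest.volume_paths:
        hits, part = search_volume(model, vol, manifest.total_residues, config)
        all_hits.extend(hits)
        if part.n_rows:
            parts.append(part)
    merged = merge_alignments(parts)
    return all_hits, merged


def run_pipeline(
    query_name: str,
    query: str,
    manifest: seqdb.VolumeManifest,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end search: seed alignment, model search over volumes, merge,
    N_eff gate, optional third iteration, coupling analysis.

    A query with no homologs terminates with the query-only alignment and an
    empty coupling result.
    """
    config = config or PipelineConfig()
    logs: list[RunLog] = []

    def log(stage: str, t0: float, n_in: int, n_out: int, **params) -> None:
        entry = RunLog(stage, time.perf_counter() - t0, n_in, n_out, params)
        logs.append(entry)
        logger.info(
            "stage=%s wall=%.2fs in=%d out=%d %s",
            entry.stage, entry.wall_time, n_in, n_out, params,
        )

    rna_query = query.upper().replace("T", "U")
    L = len(rna_query)

    t0 = time.perf_counter()
    css = predict_css(rna_query, engine=config.css_engine)
    log("css", t0, L, len(css), engine=config.css_engine)

    t0 = time.perf_counter()
    msa1 = seed_search(
        query_name, rna_query, manifest.volume_paths, manifest.total_residues, config
    )
    log("seed_search", t0, len(manifest.volume_paths), msa1.n_rows,
        evalue=config.seed_evalue)

    t0 = time.perf_counter()
    model = build_model(msa1, css, config)
    model = calibrate_model(
        model, n_null=config.n_null, null_len=config.null_len, seed=config.seed
    )
    log("model_1", t0, msa1.n_rows, model.match_length, n_null=config.n_null)

    t0 = time.perf_counter()
    hits2, msa2 = _search_all_volumes(model, manifest, config)
    log("search_2", t0, len(manifest.volume_paths), msa2.n_rows,
        evalue=config.include_evalue)

    report2 = neff(msa2, config.identity_threshold)

    if msa2.n_rows <= 1:
        # zero-hit terminal state
        return PipelineResult(
            msa=msa2, neff_report=report2, dca_result=empty_result(L),
            iterations=2, msa1=msa1, msa2=msa2, msa3=None, logs=logs,
        )

    final = msa2
    msa3 = None
    iterations = 2
    final_report = report2
    if report2.neff <= config.neff_gate:
        iterations = 3
        t0 = time.perf_counter()
        model3 = build_model(msa2, _project_css(model.css, model.match_length), config)
        if config.recalibrate:
            model3 = calibrate_model(
                model3, n_null=config.n_null, null_len=config.null_len,
                seed=config.seed,
            )
        else:
            model3 = replace(
                model3, calibration=model.calibration, null_len=model.null_len
            )
        hits3, msa3 = _search_all_volumes(model3, manifest, config)
        log("search_3", t0, len(manifest.volume_paths), msa3.n_rows,
            evalue=config.include_evalue)
        final = msa3
        final_report = neff(msa3, config.identity_threshold)

    t0 = time.perf_counter()
    if final.n_rows > 1:
        dca_result = run_mfdca(
            final, threshold=config.identity_threshold, seed=config.seed
        )
    else:
        dca_result = empty_result(L)
    log("dca", t0, final.n_rows, len(dca_result.ranked_pairs))

    return PipelineResult(
        msa=final, neff_report=final_report, dca_result=dca_result,
        iterations=iterations, msa1=msa1, msa2=msa2, msa3=msa3, logs=logs,
    )
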