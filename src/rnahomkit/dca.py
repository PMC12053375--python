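"""Mean-field direct-coupling analysis (mfDCA) of an RNA alignment.

Given a query-anchored MSA, columns are restricted to match columns where the
query holds a residue, so every score lives on 1-based query coordinates.
Sequences are reweighted by inverse 80%-identity cluster size.  With a
pseudocount of weight lambda the regularized frequencies are

    f_i(a)    = (1/(lambda+M_eff)) [ lambda/q   + sum_m w_m d(a, s_i^m) ]
    f_ij(a,b) = (1/(lambda+M_eff)) [ lambda/q^2 + sum_m w_m d(a,s_i^m) d(b,s_j^m) ]

over the q = 5 state alphabet (A, C, G, U, gap), with the single-site
pseudocount on the diagonal blocks so that f_ii(a,a) = f_i(a).  The
mean-field approximation takes the direct couplings as the negative inverse
of the connected-correlation matrix C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b)
restricted to the first q-1 states.  Each pair is then summarized by its
direct information

    DI_ij = sum_ab P_ij(a,b) ln( P_ij(a,b) / (f_i(a) f_j(b)) )

where P_ij is the two-site model built from the coupling block with fields
fitted so its marginals reproduce f_i and f_j.  Pairs closer than four
positions apart are masked as local, and the top L/3 ranked pairs are the
predicted base-pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .msa import Msa, sequence_weights, DEFAULT_IDENTITY_THRESHOLD

logger = logging.getLogger("rnahomkit.dca")

ALPHABET = "ACGU-"
Q = len(ALPHABET)  # 5: four ribonucleotides + gap as a state

#: pairs with |i - j| <= MIN_SEPARATION - 1 are considered local and masked
LOCAL_MASK_SEP = 3

#: default cap on MSA rows before DCA (uniform subsample, seeded)
DEFAULT_MAX_ROWS = 100_000

_FIELD_TOL = 1e-6
_FIELD_MAX_ITER = 500


class DcaNumericalError(RuntimeError):
    pass


@dataclass
class FrequencyModel:
    """Regularized single- and pair-column frequencies of an alignment."""

    f_i: np.ndarray  # (L, q)
    f_ij: np.ndarray  # (L, L, q, q)
    meff: float
    lam: float
    columns: np.ndarray  # original match-column indices (query coordinates)

    @property
    def length(self) -> int:
        return self.f_i.shape[0]


@dataclass
class DcaResult:
    """Symmetric direct-information matrix plus the ranked non-local pairs."""

    di: np.ndarray  # (L, L), local band zeroed
    ranked_pairs: list[tuple[int, int, float]]  # 1-based (i, j, score), i < j
    length: int

    @property
    def is_empty(self) -> bool:
        return not self.ranked_pairs


def empty_result(length: int) -> DcaResult:
    return DcaResult(np.zeros((length, length)), [], length)


# ---------------------------------------------------------------------------
# column extraction and frequencies
# ---------------------------------------------------------------------------


def query_columns(msa: Msa) -> np.ndarray:
    """Match-column positions where the query row is a residue (0-based,
    counted within match columns)."""
    if msa.query_index is None:
        raise ValueError("MSA has no designated query row")
    qrow = msa.match_only_rows()[msa.query_index]
    return np.flatnonzero(np.array([c != "-" for c in qrow]))


def encode_msa(msa: Msa) -> np.ndarray:
    """Integer-encode match columns restricted to query residues.

    Returns an (n_rows, L) array of state indices into :data:`ALPHABET`;
    T is read as U and any ambiguity character counts as a gap state.
    """
    cols = query_columns(msa)
    rows = msa.match_only_rows()
    lut = np.full(128, Q - 1, dtype=np.int8)  # default: gap state
    for k, ch in enumerate("ACGU"):
        lut[ord(ch)] = k
    lut[ord("T")] = ALPHABET.index("U")
    enc = np.empty((len(rows), cols.size), dtype=np.int8)
    for r, row in enumerate(rows):
        arr = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        enc[r] = arr[cols]
    return enc


def subsample_rows(msa: Msa, max_rows: int, seed: int) -> Msa:
    """Uniform row subsample (query always retained) to bound memory."""
    if msa.n_rows <= max_rows:
        return msa
    rng = np.random.default_rng(seed)
    pool = [i for i in range(msa.n_rows) if i != msa.query_index]
    keep = sorted(rng.choice(pool, size=max_rows - 1, replace=False).tolist())
    if msa.query_index is not None:
        keep = [msa.query_index] + keep
    logger.info("subsampled MSA from %d to %d rows", msa.n_rows, max_rows)
    return msa.take_rows(keep)


def compute_frequencies(
    msa: Msa,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    lam: float | None = None,
) -> FrequencyModel:
    """Weighted, pseudocount-regularized column and column-pair frequencies.

    ``lam`` defaults to M_eff itself (pseudocount weight 1/2), the customary
    mean-field choice.  A single-row MSA is degenerate but defined (warned).
    """
    if msa.n_rows == 0:
        raise ValueError("empty MSA")
    if msa.n_rows == 1:
        logger.warning("single-row MSA: coupling analysis is degenerate")
    enc = encode_msa(msa)
    w = sequence_weights(msa, threshold)
    meff = float(w.sum())
    if lam is None:
        lam = meff
    if lam <= 0:
        raise ValueError("pseudocount weight must be positive")
    n, L = enc.shape

    onehot = np.zeros((n, L, Q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], enc] = 1.0

    wc_i = np.tensordot(w, onehot, axes=(0, 0))  # (L, q) weighted counts
    flat = (onehot * w[:, None, None]).reshape(n, L * Q)
    wc_ij = np.tensordot(onehot.reshape(n, L * Q), flat, axes=(0, 0)).reshape(
        L, Q, L, Q
    ).transpose(0, 2, 1, 3)  # (L, L, q, q)

    norm = 1.0 / (lam + meff)
    f_i = norm * (lam / Q + wc_i)
    f_ij = norm * (lam / (Q * Q) + wc_ij)
    # diagonal blocks carry the single-site pseudocount so f_ii(a,a) = f_i(a)
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    return FrequencyModel(f_i=f_i, f_ij=f_ij, meff=meff, lam=lam,
                          columns=query_columns(msa))


# ---------------------------------------------------------------------------
# mean-field inversion
# ---------------------------------------------------------------------------


def mean_field_couplings(fm: FrequencyModel) -> np.ndarray:
    """Direct couplings e_ij(a,b) = -(C^-1)_ij(a,b) over the first q-1 states.

    Returns an (L, L, q, q) tensor with the last (gap) state gauge-fixed to
    zero; e_ij equals e_ji transposed.
    """
    L = fm.length
    qm = Q - 1
    C = (
        fm.f_ij[:, :, :qm, :qm]
        - fm.f_i[:, None, :qm, None] * fm.f_i[None, :, None, :qm]
    )
    Cmat = C.transpose(0, 2, 1, 3).reshape(L * qm, L * qm)
    try:
        inv = np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as exc:
        raise DcaNumericalError(
            "correlation matrix is singular; increase the pseudocount weight"
        ) from exc
    e = np.zeros((L, L, Q, Q))
    e[:, :, :qm, :qm] = -inv.reshape(L, qm, L, qm).transpose(0, 2, 1, 3)
    return e


def _two_site_model(
    W: np.ndarray, fi: np.ndarray, fj: np.ndarray
) -> np.ndarray:
    """P(a,b) proportional to W(a,b) x(a) y(b) with marginals (fi, fj), by
    fixed-point iteration on the compensating fields."""
    x = np.ones(Q)
    y = np.ones(Q)
    for _ in range(_FIELD_MAX_ITER):
        x_new = fi / (W @ y)
        y_new = fj / (W.T @ x_new)
        P = W * np.outer(x_new, y_new)
        P /= P.sum()
        if (
            np.abs(P.sum(axis=1) - fi).max() < _FIELD_TOL
            and np.abs(P.sum(axis=0) - fj).max() < _FIELD_TOL
        ):
            return P
        x, y = x_new, y_new
    raise DcaNumericalError("two-site field iteration did not converge")


def direct_information(
    e: np.ndarray, fm: FrequencyModel, apc: bool = False
) -> DcaResult:
    """Per-pair direct information, local band masked, ranked descending.

    With ``apc`` the average-product correction is subtracted from the DI
    matrix before ranking (off by default; plain DI is the customary mfDCA
    output).
    """
    L = fm.length
    di = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            if j - i <= LOCAL_MASK_SEP:
                continue
            if not np.any(e[i, j]):
                continue  # independence limit: DI is exactly 0
            W = np.exp(e[i, j])
            try:
                P = _two_site_model(W, fm.f_i[i], fm.f_i[j])
            except DcaNumericalError as exc:
                raise DcaNumericalError(f"pair ({i + 1},{j + 1}): {exc}") from exc
            denom = np.outer(fm.f_i[i], fm.f_i[j])
            val = float(np.sum(P * np.log(P / denom)))
            di[i, j] = di[j, i] = max(val, 0.0)

    score = di.copy()
    if apc:
        nonlocal_mask = np.abs(np.subtract.outer(range(L), range(L))) > LOCAL_MASK_SEP
        mean_all = score[nonlocal_mask].mean() if nonlocal_mask.any() else 0.0
        col_mean = np.where(
            nonlocal_mask.sum(axis=1) > 0,
            score.sum(axis=1) / np.maximum(nonlocal_mask.sum(axis=1), 1),
            0.0,
        )
        if mean_all > 0:
            score = score - np.outer(col_mean, col_mean) / mean_all

    ranked = sorted(
        (
            (i + 1, j + 1, float(score[i, j]))
            for i in range(L)
            for j in range(i + LOCAL_MASK_SEP + 1, L)
        ),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    return DcaResult(di=di, ranked_pairs=ranked, length=L)


def top_pairs(result: DcaResult, L: int | None = None) -> list[tuple[int, int]]:
    """The first floor(L/3) ranked non-local pairs (at least one)."""
    if L is None:
        L = result.length
    k = max(1, L // 3)
    return [(i, j) for i, j, _ in result.ranked_pairs[:k]]


def run_mfdca(
    msa: Msa,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    lam: float | None = None,
    apc: bool = False,
    max_rows: int = DEFAULT_MAX_ROWS,
    seed: int = 0,
) -> DcaResult:
    """Full mfDCA: subsample, frequencies, mean-field inversion, DI ranking."""
    msa = subsample_rows(msa, max_rows, seed)
    fm = compute_frequencies(msa, threshold=threshold, lam=lam)
    e = mean_field_couplings(fm)
    return direct_information(e, fm, apc=apc)


def write_pairs_tsv(result: DcaResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for i, j, s in result.ranked_pairs:
            fh.write(f"{i}\t{j}\t{s:.6g}\n")
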