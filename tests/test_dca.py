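"""Mean-field coupling analysis: frequencies, couplings, direct information."""

import numpy as np
import pytest

import rnahomkit as rk
from rnahomkit.dca import (
    ALPHABET,
    Q,
    DcaResult,
    compute_frequencies,
    direct_information,
    mean_field_couplings,
    run_mfdca,
    top_pairs,
)
from rnahomkit.msa import Msa

from conftest import random_msa


def _msa(rows, query_index=0):
    return Msa(
        [f"s{i}" for i in range(len(rows))],
        rows,
        np.ones(len(rows[0]), dtype=bool),
        query_index=query_index,
    )


def test_single_row_frequency_formula():
    """One row 'AC' with lambda = M_eff = 1: f_1(A) = (1/2)(1/5 + 1) = 0.6."""
    fm = compute_frequencies(_msa(["AC"]), lam=1.0)
    assert fm.meff == pytest.approx(1.0)
    assert fm.f_i[0, ALPHABET.index("A")] == pytest.approx(0.6)
    assert fm.f_i[0, ALPHABET.index("C")] == pytest.approx(0.1)
    assert fm.f_i[1, ALPHABET.index("C")] == pytest.approx(0.6)


def test_frequencies_normalized_and_consistent():
    m = random_msa(30, 12, seed=5)
    m.query_index = 0
    m.rows[0] = m.rows[0].replace("-", "A")  # gapless query: all columns kept
    fm = compute_frequencies(m)
    assert np.allclose(fm.f_i.sum(axis=1), 1.0)
    assert np.allclose(fm.f_ij.sum(axis=(2, 3)), 1.0)
    L = fm.length
    for i in range(L):
        assert np.allclose(np.diag(fm.f_ij[i, i]), fm.f_i[i])
    assert fm.f_i.min() > 0 and fm.f_i.max() < 1


def test_frequencies_match_weighted_counting_oracle():
    """Regularized frequencies equal a direct per-sequence counting loop."""
    m = random_msa(15, 8, seed=6)
    m.query_index = 0
    m.rows[0] = m.rows[0].replace("-", "G")
    fm = compute_frequencies(m)
    from rnahomkit.msa import sequence_weights

    w = sequence_weights(m, 0.8)
    meff = w.sum()
    lam = meff
    # brute-force single-column counts
    for i in range(fm.length):
        for a, ch in enumerate(ALPHABET):
            count = sum(
                w[r]
                for r, row in enumerate(m.rows)
                if (row[i] if row[i] in "ACGU" else "-") == ch
            )
            expected = (lam / Q + count) / (lam + meff)
            assert fm.f_i[i, a] == pytest.approx(expected)


def test_uniform_msa_frequencies_approach_one_over_q():
    """On i.i.d. uniform columns (no gaps) the residue frequencies approach
    1/4 weight-shared with the pseudocount."""
    rng = np.random.default_rng(8)
    rows = ["".join(rng.choice(list("ACGU"), size=6)) for _ in range(5000)]
    m = _msa(rows)
    fm = compute_frequencies(m, lam=0.0 + 1e-9)
    # raw frequencies (tiny pseudocount): each base ~1/4, gap ~0
    se = 3 * np.sqrt(0.25 * 0.75 / 5000)
    assert np.all(np.abs(fm.f_i[:, :4] - 0.25) < se + 0.01)
    assert np.all(fm.f_i[:, 4] < 0.01)


def test_couplings_on_independent_columns_are_small():
    """Statistically independent columns give near-zero couplings."""
    rng = np.random.default_rng(3)
    rows = ["".join(rng.choice(list("ACGU"), size=10)) for _ in range(800)]
    m = _msa(rows)
    fm = compute_frequencies(m)
    e = mean_field_couplings(fm)
    off = np.array(
        [np.abs(e[i, j]).max() for i in range(10) for j in range(10) if i != j]
    )
    # noise floor: same statistic after destroying any residual pairing
    # structure by independently permuting each column's residues
    cols = np.array([list(r) for r in rows])
    for c in range(cols.shape[1]):
        cols[:, c] = cols[rng.permutation(cols.shape[0]), c]
    m2 = _msa(["".join(r) for r in cols])
    e2 = mean_field_couplings(compute_frequencies(m2))
    off2 = np.array(
        [np.abs(e2[i, j]).max() for i in range(10) for j in range(10) if i != j]
    )
    assert off.max() < 3 * off2.max()


def test_couplings_equal_closed_form_inverse_for_l2():
    """For L=2 the coupling block is the negative inverse of the 8x8
    connected-correlation matrix, computed independently via sympy."""
    import sympy

    m = _msa(["AC", "AU", "GC", "GU", "AC", "GU"])
    fm = compute_frequencies(m)
    e = mean_field_couplings(fm)
    qm = Q - 1
    C = np.zeros((2 * qm, 2 * qm))
    for i in range(2):
        for j in range(2):
            C[i * qm : (i + 1) * qm, j * qm : (j + 1) * qm] = (
                fm.f_ij[i, j, :qm, :qm]
                - np.outer(fm.f_i[i, :qm], fm.f_i[j, :qm])
            )
    inv = np.array(sympy.Matrix(C).inv(), dtype=float)
    expected = -inv[0:qm, qm : 2 * qm]
    assert np.allclose(e[0, 1, :qm, :qm], expected, atol=1e-8)


def test_couplings_symmetric_under_pair_transpose():
    m = random_msa(25, 9, seed=10)
    m.query_index = 0
    m.rows[0] = m.rows[0].replace("-", "C")
    fm = compute_frequencies(m)
    e = mean_field_couplings(fm)
    for i in range(fm.length):
        for j in range(fm.length):
            assert np.allclose(e[i, j], e[j, i].T)


def test_zero_couplings_give_zero_di():
    """With e = 0 the two-site model factorizes and DI vanishes."""
    m = random_msa(20, 12, seed=13)
    m.query_index = 0
    m.rows[0] = m.rows[0].replace("-", "U")
    fm = compute_frequencies(m)
    e = np.zeros((fm.length, fm.length, Q, Q))
    res = direct_information(e, fm)
    assert np.allclose(res.di, 0.0, atol=1e-9)


def test_di_symmetric_and_nonnegative(planted_family):
    m, _ = planted_family
    sub = m.take_rows(range(60))
    res = run_mfdca(sub)
    assert np.allclose(res.di, res.di.T)
    assert res.di.min() >= 0.0


def test_local_pairs_are_masked(planted_family):
    m, _ = planted_family
    res = run_mfdca(m.take_rows(range(50)))
    for i, j, _ in res.ranked_pairs:
        assert j - i > 3
    L = res.length
    for i in range(L):
        for j in range(i, min(i + 4, L)):
            assert res.di[i, j] == 0.0


def test_planted_pair_outranks_background(planted_family):
    """Every planted pair's DI exceeds the median DI of unplanted pairs."""
    m, structure = planted_family
    res = run_mfdca(m)
    truth = structure.nonlocal_pairs().pairs
    di = {(i, j): s for i, j, s in res.ranked_pairs}
    background = np.median([s for (i, j), s in di.items() if (i, j) not in truth])
    planted = [di[p] for p in truth if p in di]
    assert min(planted) > background


def test_di_invariant_under_row_permutation_and_duplication(planted_family):
    m, _ = planted_family
    sub = m.take_rows(range(40))
    base = run_mfdca(sub)
    rng = np.random.default_rng(1)
    # permute the non-query rows (the query stays row 0, fixing the columns)
    order = [0] + (1 + rng.permutation(39)).tolist()
    res_perm = run_mfdca(sub.take_rows(order))
    assert np.allclose(res_perm.di, base.di, atol=1e-8)
    # duplicating the whole MSA halves weights, leaves frequencies unchanged
    sub2 = Msa(sub.names + ["d" + n for n in sub.names], sub.rows * 2,
               sub.match_columns, query_index=0)
    res_dup = run_mfdca(sub2)
    assert np.allclose(res_dup.di, base.di, atol=1e-8)


def test_top_pairs_count_rules():
    ranked = [(1, 6, 5.0), (2, 7, 4.0), (3, 8, 3.0), (1, 9, 2.0), (2, 9, 1.0)]
    res = DcaResult(np.zeros((9, 9)), ranked, 9)
    assert top_pairs(res, L=9) == [(1, 6), (2, 7), (3, 8)]
    assert top_pairs(res, L=3) == [(1, 6)]  # floor(3/3)=1, minimum one


def test_equal_scores_break_ties_lexicographically():
    """With zero couplings every pair scores exactly 0 and the ranking must
    fall back to (i, j) lexicographic order."""
    m = random_msa(10, 9, seed=2, gap_frac=0.0)
    m.query_index = 0
    fm = compute_frequencies(m)
    res = direct_information(np.zeros((9, 9, Q, Q)), fm)
    pairs = [(i, j) for i, j, _ in res.ranked_pairs]
    assert all(s == 0.0 for _, _, s in res.ranked_pairs)
    assert pairs == sorted(pairs)
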