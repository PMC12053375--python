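import numpy as np
import pytest

import rnahomkit as rk
from rnahomkit import synth


@pytest.fixture(scope="session")
def planted_family():
    """200-member family, L=60, sub rate 0.15, compensatory prob 0.97."""
    spec = rk.FamilySpec(
        length=60, n_members=200, sub_rate=0.15, compensatory_prob=0.97, seed=7
    )
    msa, structure = rk.family_msa(spec)
    return msa, structure


@pytest.fixture(scope="session")
def toy_db(tmp_path_factory):
    """Small database: one 60-member family among 140 decoys, 2 volumes."""
    td = tmp_path_factory.mktemp("toydb")
    spec = rk.FamilySpec(
        length=60, n_members=60, sub_rate=0.15, compensatory_prob=0.97, seed=3
    )
    return synth.make_toy_db([spec], n_decoys=140, out_dir=td, n_volumes=2, seed=3)


def random_msa(n_rows: int, n_cols: int, seed: int, gap_frac: float = 0.1) -> rk.Msa:
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU-"))
    probs = [(1 - gap_frac) / 4] * 4 + [gap_frac]
    rows = [
        "".join(rng.choice(alphabet, size=n_cols, p=probs)) for _ in range(n_rows)
    ]
    return rk.Msa(
        names=[f"s{i}" for i in range(n_rows)],
        rows=rows,
        match_columns=np.ones(n_cols, dtype=bool),
    )
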