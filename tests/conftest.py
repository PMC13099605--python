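"""Shared fixtures and independent oracles.

The brute-force oracles here deliberately re-derive quantities by
enumeration or direct arithmetic, independent of the library's
implementation paths, so round-trip tests are genuine cross-checks.
"""

from itertools import product

import numpy as np
import pandas as pd
import pytest


def chain_pmf_bruteforce(p: float, alpha: float, n_sites: int = 8) -> np.ndarray:
    """Exact preference-chain pmf by summing over all 2^n ordered fill
    sequences: first site is His with probability p; thereafter the odds of
    repeating the previous species are multiplied by alpha."""
    p_hh = alpha * p / (alpha * p + (1 - p))
    p_sh = p / (p + alpha * (1 - p))
    pmf = np.zeros(n_sites + 1)
    for seq in product((0, 1), repeat=n_sites):
        prob = p if seq[0] else (1 - p)
        for prev, cur in zip(seq, seq[1:]):
            p_his = p_hh if prev else p_sh
            prob *= p_his if cur else (1 - p_his)
        pmf[sum(seq)] += prob
    return pmf


@pytest.fixture
def chain_oracle():
    return chain_pmf_bruteforce


def make_records(rows: list[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Tidy blot-record frame from (replicate, stage, antibody, intensity)."""
    return pd.DataFrame(rows, columns=["replicate", "stage", "antibody", "intensity"])


@pytest.fixture
def perfect_column_records():
    """One replicate, lossless columns: 100 units of His- and Strep-tagged
    Rubisco in the soluble pool, 60 units dual-tagged surviving both
    columns."""
    return make_records(
        [
            ("r1", "soluble", "anti_his", 100.0),
            ("r1", "soluble", "anti_strep", 100.0),
            ("r1", "post_his", "anti_his", 100.0),
            ("r1", "post_his", "anti_strep", 60.0),
            ("r1", "post_strep", "anti_his", 60.0),
            ("r1", "post_strep", "anti_strep", 60.0),
        ]
    )
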