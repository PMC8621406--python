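import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

import stagetraffic as st

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities
    of all tables with the same margins that are no more probable than the
    observed one.  Independent of scipy.stats.fisher_exact.
    """
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(k: int) -> float:
        return comb(row1, k) * comb(row2, col1 - k) / denom

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


@pytest.fixture(scope="session")
def small_universe():
    """A seeded synthetic universe with pairs, shared across tests."""
    cfg = st.SynthConfig(seed=11)
    annot, labels = st.generate_universe(cfg)
    pair_table, annot, labels = st.generate_pairs(annot, labels, cfg)
    return cfg, annot, labels, pair_table


@pytest.fixture(scope="session")
def small_run(small_universe):
    """Counts, profile and categories for the shared universe."""
    cfg, annot, labels, pair_table = small_universe
    data = st.generate_counts(labels, cfg)
    filtered = st.qc_filter(data)
    profile = st.aggregate(filtered)
    categories = st.classify_genes(profile)
    return data, filtered, profile, categories


def toy_counts(matrix, cell_types, gene_ids=None, cell_ids=None):
    matrix = np.asarray(matrix)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(matrix.shape[1])]
    return st.LabeledCounts(
        counts=sp.csr_matrix(matrix),
        cell_types=np.asarray(cell_types, dtype=object),
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=None if cell_ids is None else np.asarray(cell_ids, dtype=object),
    )


def balanced_cell_types(n_per_type: int) -> np.ndarray:
    out = []
    for ct in st.CELL_TYPES:
        out.extend([ct] * n_per_type)
    return np.asarray(out, dtype=object)
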