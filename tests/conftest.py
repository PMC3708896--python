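"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import triadexpr as tx

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Independent oracles (direct summation / enumeration; no shared code path
# with the package implementation)
# ---------------------------------------------------------------------------


def ac_pmf_oracle(x: int, y: int, n1: float, n2: float) -> float:
    """Audic-Claverie pmf evaluated by the direct log-factorial formula."""
    r = n2 / n1
    return math.exp(
        y * math.log(r)
        + math.lgamma(x + y + 1)
        - math.lgamma(x + 1)
        - math.lgamma(y + 1)
        - (x + y + 1) * math.log1p(r)
    )


def ac_test_oracle(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided tail-doubled p-value by brute-force pmf summation.

    Uses the same canonical orientation as the implementation (condition
    on the larger library's count; tie in totals -> the smaller count) but
    sums the pmf term by term instead of using incomplete-beta tails.
    """
    if n1 > n2:
        ref_c, ref_n, obs_c, obs_n = x, n1, y, n2
    elif n2 > n1:
        ref_c, ref_n, obs_c, obs_n = y, n2, x, n1
    else:
        ref_c, obs_c = min(x, y), max(x, y)
        ref_n = obs_n = n1
    lower = sum(ac_pmf_oracle(ref_c, k, ref_n, obs_n) for k in range(obs_c + 1))
    upper = 1.0 - lower + ac_pmf_oracle(ref_c, obs_c, ref_n, obs_n)
    return min(1.0, 2.0 * min(lower, upper))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return math.exp(
            math.lgamma(col1 + 1)
            - math.lgamma(k + 1)
            - math.lgamma(col1 - k + 1)
            + math.lgamma(n - col1 + 1)
            - math.lgamma(row1 - k + 1)
            - math.lgamma(n - col1 - (row1 - k) + 1)
            - (math.lgamma(n + 1) - math.lgamma(row1 + 1) - math.lgamma(n - row1 + 1))
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9)))


@pytest.fixture
def oracles():
    return {
        "ac_pmf": ac_pmf_oracle,
        "ac_test": ac_test_oracle,
        "fisher": fisher_two_sided_oracle,
    }


# ---------------------------------------------------------------------------
# Dataset helpers
# ---------------------------------------------------------------------------


def make_dataset(**kwargs):
    """Simulate a (catalog, truth, counts) bundle with overridable config."""
    cfg = tx.SimulationConfig(**kwargs)
    return cfg, *tx.simulate_dataset(cfg)


@pytest.fixture
def small_dataset():
    """A light simulated bundle shared by smoke-level tests."""
    cfg, catalog, truth, counts = make_dataset(
        n_genes=800, library_sizes=(200_000, 180_000, 190_000), seed=42
    )
    rpkm = tx.compute_rpkm(counts, catalog)
    return {
        "config": cfg,
        "catalog": catalog,
        "truth": truth,
        "counts": counts,
        "rpkm": rpkm,
    }


def flat_count_matrix(columns: dict, totals: dict | None = None) -> tx.CountMatrix:
    """Build a CountMatrix from per-library integer arrays."""
    n = len(next(iter(columns.values())))
    ids = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
    frame = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in columns.items()}, index=ids)
    return tx.CountMatrix.from_frame(frame, totals=totals)


def uniform_catalog(gene_ids, length_bp: int = 1000) -> pd.DataFrame:
    return pd.DataFrame({"gene_id": list(gene_ids), "length_bp": length_bp})
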