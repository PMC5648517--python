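"""Shared fixtures: small count matrices and a reusable synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirlink.ioformats import CountMatrix


@pytest.fixture()
def six_sample_stages() -> pd.Series:
    return pd.Series(
        ["immature"] * 3 + ["pubertal"] * 3,
        index=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


@pytest.fixture()
def toy_counts(six_sample_stages) -> CountMatrix:
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.poisson(100, size=(20, 6)),
        index=[f"f{i:02d}" for i in range(20)],
        columns=six_sample_stages.index,
    )
    return CountMatrix(counts, six_sample_stages)


def brute_force_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg from first principles: sort, scale by m/rank,
    cumulative minimum from the largest p downward, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj
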