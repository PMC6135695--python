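"""Shared fixtures: scaled synthetic cohorts and naive clustering oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from epigenotyper.synthetic import CohortConfig, fast_cohort_config, generate_cohort


@pytest.fixture(scope="session")
def scaled_config() -> CohortConfig:
    """Cohort scaled to ~100 samples x ~300 genes for fast recovery tests."""
    return fast_cohort_config()


@pytest.fixture(scope="session")
def scaled_cohort(scaled_config):
    return generate_cohort(scaled_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (study-scale sample and gene counts)."""
    return generate_cohort(seed=7)


def naive_hierarchical(X: np.ndarray, metric: str, method: str):
    """Exhaustive agglomerative clustering oracle for small inputs.

    Returns (merge heights in order, cophenetic distance matrix).  Distances:
    'correlation' (1 - Pearson r) or 'cityblock'; linkage: 'average' (mean of
    all original-point pair distances) or 'complete' (max).
    """
    n = X.shape[0]
    if metric == "correlation":
        base = 1.0 - np.corrcoef(X)
    elif metric == "cityblock":
        base = np.array([[np.abs(X[i] - X[j]).sum() for j in range(n)] for i in range(n)])
    else:  # pragma: no cover - oracle guard
        raise ValueError(metric)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    heights = []
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pair_d = [base[i, j] for i in clusters[a] for j in clusters[b]]
            d = float(np.mean(pair_d)) if method == "average" else float(np.max(pair_d))
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights, coph
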