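"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's vectorized code paths:
they loop over units, latent abundances and occasions with scipy.stats pmfs
(or pure-Python combinatorics), so agreement is a genuine cross-check.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from biopyramid.detections import DetectionHistory


def make_history(
    counts,
    effort=None,
    species: str = "sp",
    period_days: int = 5,
    stations=None,
) -> DetectionHistory:
    """DetectionHistory from a plain counts matrix (full effort by default)."""
    counts = np.asarray(counts, dtype=float)
    n, T = counts.shape
    if effort is None:
        effort = np.full((n, T), period_days)
    effort = np.asarray(effort, dtype=int)
    counts = counts.copy()
    counts[effort == 0] = np.nan
    units = [f"u{i}" for i in range(n)]
    if stations is None:
        stations = [f"s{i}" for i in range(n)]
    cov = pd.DataFrame({"station_id": stations, "year": 2020}, index=units)
    return DetectionHistory(
        species=species, units=units, counts=counts, effort=effort,
        unit_covariates=cov, period_days=period_days,
    )


def naive_marginal_loglik(counts, mask, p, lam, K) -> float:
    """Brute-force triple loop over units, latent N and occasions.

    p is (n, T) per-occasion detection probability, lam length-n expected
    abundance.  Pure-Python binomial/Poisson pmfs.
    """
    counts = np.asarray(counts, dtype=float)
    n, T = counts.shape
    total = 0.0
    for i in range(n):
        s = 0.0
        for N in range(K + 1):
            log_term = -lam[i] + N * math.log(lam[i]) - math.lgamma(N + 1)
            ok = True
            for t in range(T):
                if not mask[i, t]:
                    continue
                y = int(counts[i, t])
                if y > N:
                    ok = False
                    break
                log_term += (
                    math.lgamma(N + 1) - math.lgamma(y + 1) - math.lgamma(N - y + 1)
                    + y * math.log(p[i, t]) + (N - y) * math.log1p(-p[i, t])
                )
            if ok:
                s += math.exp(log_term)
        total += math.log(s)
    return total


@pytest.fixture(scope="session")
def traits():
    from biopyramid.datasets import load_synthetic_traits

    return load_synthetic_traits()


@pytest.fixture(scope="session")
def reference():
    from biopyramid.datasets import load_reference_estimates

    return load_reference_estimates()
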