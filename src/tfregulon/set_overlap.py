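"""Hypergeometric overlap between regulated-target sets.

The similarity of two gene sets A and B within a universe of N genes is
measured by the normal-approximation z of the hypergeometric overlap count
k = |A ∩ B|:

    mu     = n*K/N
    sigma^2 = n*K*(N-n)*(N-K) / (N^2 * (N-1))
    z      = (k - mu) / sigma          (z = 0 when sigma = 0)

with n = |A|, K = |B|.  The pairwise matrix over per-TF up/down target sets
is signed: comparisons between two downregulated sets are multiplied by -1,
a display convention that separates repression-side similarity from
activation-side similarity; mixed up/down pairs keep the positive sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_z(k: int, n: int, K: int, N: int) -> float:
    """Normal-approximation z for an overlap of k in the hypergeometric
    (N, K, n) model; 0 for degenerate (zero-variance) configurations."""
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError("set sizes must lie in [0, N]")
    if not (0 <= k <= min(n, K)):
        raise ValueError("overlap k outside [0, min(n, K)]")
    if N == 1:
        return 0.0
    mu = n * K / N
    var = n * K * (N - n) * (N - K) / (N ** 2 * (N - 1))
    if var <= 0:
        return 0.0
    return float((k - mu) / np.sqrt(var))


def hypergeom_exact_p(k: int, n: int, K: int, N: int) -> float:
    """Exact two-sided hypergeometric p (doubled smaller tail, capped at 1).

    Reference oracle for the normal approximation; not used by the pipeline.
    """
    rv = stats.hypergeom(N, K, n)
    upper = rv.sf(k - 1)   # P(X >= k)
    lower = rv.cdf(k)      # P(X <= k)
    return float(min(1.0, 2.0 * min(upper, lower)))


def similarity_matrix(sets: list[tuple[str, str, frozenset | set]],
                      universe) -> pd.DataFrame:
    """Signed pairwise hypergeometric z over (tf, direction, gene set) rows.

    ``universe`` is the full gene collection (or its size).  Rows/columns
    are labelled ``TF_up`` / ``TF_down``; the diagonal is NaN, and rows for
    empty sets are NaN (not computable).  Down-vs-down entries carry sign
    -1.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    N = universe if isinstance(universe, int) else len(universe)
    labels = [f"{tf}_{direction}" for tf, direction, _ in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (tf, direction) labels")
    z = np.full((len(sets), len(sets)), np.nan)
    for i, (_, dir_i, a) in enumerate(sets):
        for j, (_, dir_j, b) in enumerate(sets):
            if i == j or len(a) == 0 or len(b) == 0:
                continue
            val = hypergeom_z(len(set(a) & set(b)), len(a), len(b), N)
            if dir_i == "down" and dir_j == "down":
                val = -val
            z[i, j] = val
    return pd.DataFrame(z, index=labels, columns=labels)
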