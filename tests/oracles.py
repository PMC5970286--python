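"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the nonwear oracle
is a direct linear scan, and the WLS oracle is the closed-form normal
equation solved with numpy.
"""

from __future__ import annotations

import numpy as np


def nonwear_runs_oracle(missing: np.ndarray, min_gap: int = 90) -> list[tuple[int, int]]:
    """(start, length) of every maximal missing run >= min_gap, by direct scan."""
    runs = []
    i, n = 0, len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            if j - i >= min_gap:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def wls_slope_oracle(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted least-squares slope (with intercept) via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return float(beta[1])


def ols_slope_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form simple-regression slope: cov(x, y) / var(x)."""
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc**2).sum())
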