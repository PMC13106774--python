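"""Natural cubic spline basis for the time trends of the cost regressions."""

from __future__ import annotations

import numpy as np


def natural_cubic_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Returns a design matrix with ``len(knots) - 1`` columns: the linear term
    followed by the ``len(knots) - 2`` restricted truncated-power terms of the
    standard natural-spline construction.  With ``K`` knots the fitted curve
    has the usual ``K - 1`` degrees of freedom beyond the intercept.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or len(k) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    kmax = k[-1]
    kprev = k[-2]

    def d(j):
        return (np.clip(x - k[j], 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3) / (kmax - k[j])

    dlast = d(len(k) - 2)
    cols = [x] + [d(j) - dlast for j in range(len(k) - 2)]
    return np.column_stack(cols)


def spline_curve(x, knots, coefficients) -> np.ndarray:
    """Evaluate the spline (no intercept) at ``x``."""
    B = natural_cubic_basis(x, knots)
    c = np.asarray(coefficients, dtype=float)
    if B.shape[1] != len(c):
        raise ValueError(f"expected {B.shape[1]} coefficients, got {len(c)}")
    return B @ c
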