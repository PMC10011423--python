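"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a Pearson correlation via the Fisher z-transform.

    Requires n > 3 pairs; the interval is symmetric on the z scale.
    """
    from scipy.stats import norm

    if n <= 3:
        return (float("nan"), float("nan"))
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    se = 1.0 / np.sqrt(n - 3)
    crit = norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic start x ~ 0.5 + 1/y, which is accurate for small y;
    for very large y (x near 0) trigamma(x) ~ 1/x^2 gives the start instead.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)
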