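"""Exact 2x2 contingency statistics shared across the pipeline.

Fisher's exact test is computed by direct hypergeometric enumeration with
integer arithmetic, so p-values are exact up to float rounding of a single
ratio of big integers.  The two-sided p sums all tables in the conditional
support whose probability does not exceed that of the observed table, with
ties resolved exactly (no floating-point tie tolerance).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "fisher_exact_2x2",
    "chi2_or_fisher",
    "benjamini_hochberg",
]


def _validate_table(table) -> tuple[int, int, int, int]:
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table entries must be non-negative")
    return a, b, c, d


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Exact Fisher p-value for a 2x2 table ``[[a, b], [c, d]]``.

    ``alternative='greater'`` tests enrichment of the top-left cell
    (odds ratio > 1), ``'less'`` the reverse; ``'two-sided'`` uses the
    minimum-likelihood rule on the conditional hypergeometric support.
    """
    a, b, c, d = _validate_table(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    # integer numerators of the hypergeometric pmf; common denominator C(n, c1)
    numerators = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    denom = comb(n, c1)
    obs = numerators[a]
    if alternative == "greater":
        num = sum(v for k, v in numerators.items() if k >= a)
    elif alternative == "less":
        num = sum(v for k, v in numerators.items() if k <= a)
    elif alternative == "two-sided":
        num = sum(v for v in numerators.values() if v <= obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = Fraction(num, denom)
    return float(min(p, Fraction(1)))


def chi2_or_fisher(table, alternative: str = "two-sided") -> tuple[float, str]:
    """Chi-square test when all expected cells are >= 5, else exact Fisher.

    Returns ``(p, method)`` with ``method`` in {"chi2", "fisher"}.  The
    chi-square branch is two-sided by construction; a one-sided request
    forces the Fisher branch.
    """
    a, b, c, d = _validate_table(table)
    arr = np.array([[a, b], [c, d]], dtype=float)
    n = arr.sum()
    if n == 0:
        return 1.0, "fisher"
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if alternative == "two-sided" and (expected >= 5).all():
        _, p, _, _ = _scipy_stats.chi2_contingency(arr, correction=False)
        return float(p), "chi2"
    return fisher_exact_2x2(table, alternative=alternative), "fisher"


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up q-values (monotone adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
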