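"""Exact enrichment statistics shared by the tree filter and virophage analyses.

``fisher_exact_greater`` is the one-sided (enrichment) Fisher exact test,
evaluated in exact rational arithmetic for small tables and as a log-space
hypergeometric tail sum for large ones, so p-values are reproducible to
machine precision on the clade sizes the pipeline produces.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

import numpy as np

from .containers import ContingencyTable2x2

__all__ = ["fisher_exact_greater", "bh_adjust"]

#: Tables with total at most this size use exact rational arithmetic.
_EXACT_TOTAL = 64


def _table(t) -> tuple[int, int, int, int]:
    if isinstance(t, ContingencyTable2x2):
        return t.a, t.b, t.c, t.d
    a, b, c, d = t
    return int(a), int(b), int(c), int(d)


def fisher_exact_greater(table) -> float:
    """One-sided Fisher exact p-value for enrichment of the 'a' cell.

    With the table ``(a, b, c, d)`` (in-group associated / in-group not /
    out-group associated / out-group not), returns ``P(X >= a)`` where X is
    hypergeometric with population ``a+b+c+d``, ``a+c`` successes and
    ``a+b`` draws.
    """
    a, b, c, d = _table(table)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    n_pop = a + b + c + d
    k_succ = a + c
    n_draw = a + b
    lo = max(0, n_draw - (n_pop - k_succ))
    hi = min(k_succ, n_draw)
    if a <= lo:
        return 1.0
    if n_pop <= _EXACT_TOTAL:
        numer = sum(math.comb(k_succ, k) * math.comb(n_pop - k_succ, n_draw - k)
                    for k in range(a, hi + 1))
        return float(Fraction(numer, math.comb(n_pop, n_draw)))
    log_denom = _lchoose(n_pop, n_draw)
    logs = [_lchoose(k_succ, k) + _lchoose(n_pop - k_succ, n_draw - k) - log_denom
            for k in range(a, hi + 1)]
    peak = max(logs)
    p = math.exp(peak) * math.fsum(math.exp(l - peak) for l in logs)
    return min(1.0, p)


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} (m / j) * p_(j)``, capped at 1 and mapped back to
    the input order.  Ties are handled by the stable sort, which makes the
    result order-independent.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.minimum(q_sorted, 1.0, out=q_sorted)
    out = np.empty(m)
    out[order] = q_sorted
    return out
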