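"""Benjamini-Hochberg FDR control over the family of primary IVW tests.

The family is all cytokine-by-outcome IVW tests within one instrument
definition; a q-value not greater than the threshold (default 10%) is
declared significant (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


def bh_qvalues(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorting ascending, q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, and
    mapped back to the input order. Ties share the smaller rank's adjusted
    value through the min-cascade. Permutation equivariant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise DomainError("pvalues must be a non-empty 1-d sequence")
    bad = np.flatnonzero(~((p > 0) & (p <= 1)))
    if bad.size:
        raise DomainError(f"p-value outside (0,1] at index {int(bad[0])}: {p[bad[0]]}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return [float(v) for v in q]


def flag_significant(qvalues, q_max: float = 0.10) -> list[bool]:
    """Elementwise q <= q_max (the threshold itself is significant)."""
    return [bool(q <= q_max) for q in qvalues]


@dataclass
class QValueTable:
    """FDR-adjusted p-values for a family of tests, with significance flags."""

    test_ids: list[str]
    pvalues: list[float]
    qvalues: list[float]
    significant: list[bool]


def qvalue_table(test_ids, pvalues, q_max: float = 0.10) -> QValueTable:
    q = bh_qvalues(pvalues)
    return QValueTable(list(test_ids), [float(p) for p in pvalues], q, flag_significant(q, q_max))
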