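"""Exact hypergeometric machinery shared by the comorbidity and gene-overlap tests.

The Fisher exact test is evaluated in log-space so that tables with totals in
the millions (a full hospital roster) remain numerically stable: cell counts
enter only through log-factorials, never through factorials themselves.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = ["fisher_exact_from_margins", "hypergeom_log_pmf"]

# Relative slack when comparing a candidate table's probability with the
# observed table's: without it, floating-point noise can exclude the observed
# table from its own two-sided sum.
_TIE_REL_TOL = 1e-7


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def hypergeom_log_pmf(total: int, n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every table with margins ``(n1, n2, total)``.

    Returns ``(support, log_pmf)`` where ``support`` holds the feasible values
    of the both-diseases cell ``d`` and ``log_pmf[i]`` the hypergeometric
    log-probability of ``d = support[i]``.
    """
    lo = max(0, n1 + n2 - total)
    hi = min(n1, n2)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_comb(n1, support)
        + _log_comb(total - n1, n2 - support)
        - _log_comb(total, n2)
    )
    return support, log_pmf


def fisher_exact_from_margins(
    total: int, n1: int, n2: int, d: int, alternative: str = "two-sided"
) -> float:
    """Fisher exact p-value for the 2x2 table with margins n1, n2 and cell d.

    ``alternative`` is one of ``two-sided`` (sum of all tables no more probable
    than the observed one, the classical definition), ``greater`` (upper tail,
    d or more shared) or ``less``.  Degenerate margins (an empty row or column)
    give p = 1: only one table is possible.
    """
    if not (0 <= n1 <= total and 0 <= n2 <= total):
        raise ValueError(f"margins out of range: n1={n1}, n2={n2}, total={total}")
    if not (max(0, n1 + n2 - total) <= d <= min(n1, n2)):
        raise ValueError(f"cell d={d} infeasible for margins n1={n1}, n2={n2}, N={total}")
    if n1 > n2:  # the margins are exchangeable; fix an order so p is exactly symmetric
        n1, n2 = n2, n1
    support, log_pmf = hypergeom_log_pmf(total, n1, n2)
    if support.size == 1:
        return 1.0
    obs = log_pmf[d - support[0]]
    if alternative == "two-sided":
        mask = log_pmf <= obs + math.log1p(_TIE_REL_TOL)
    elif alternative == "greater":
        mask = support >= d
    elif alternative == "less":
        mask = support <= d
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    # log-sum-exp over the selected tables
    selected = log_pmf[mask]
    m = selected.max()
    p = math.exp(m) * float(np.exp(selected - m).sum())
    return min(p, 1.0)
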