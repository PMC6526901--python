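"""Exact and Monte-Carlo conditional tests for r x c contingency tables."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    """Log probability of a table under fixed margins (hypergeometric)."""
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums, limit):
    """Yield all non-negative integer tables with the given margins.

    Recursive row-by-row enumeration; raises ``OverflowError`` once more
    than ``limit`` tables have been produced.
    """
    r, c = len(row_sums), len(col_sums)
    count = 0

    def rows(remaining_cols, i):
        nonlocal count
        if i == r - 1:
            last = np.array(remaining_cols)
            if (last >= 0).all() and last.sum() == row_sums[i]:
                count += 1
                if count > limit:
                    raise OverflowError
                yield [tuple(last)]
            return
        for fill in _row_fills(row_sums[i], remaining_cols, c):
            rest = [remaining_cols[j] - fill[j] for j in range(c)]
            for tail in rows(rest, i + 1):
                yield [fill] + tail

    yield from rows(list(col_sums), 0)


def _row_fills(total, caps, c):
    """All ways to write `total` as c non-negative parts bounded by caps."""
    if c == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    for first in range(min(total, caps[0]) + 1):
        for rest in _row_fills(total - first, caps[1:], c - 1):
            yield (first,) + rest


def rxc_fisher_exact(
    table, seed: int = 0, n_mc: int = 20000, enumeration_limit: int = 200000
) -> float:
    """Two-sided Fisher exact p-value for an r x c table.

    2x2 tables go through scipy.  Larger tables are enumerated exactly when
    the conditional table space is small enough; otherwise a margin-
    conditional Monte-Carlo estimate (sequential multivariate hypergeometric
    rows, fixed seed) is returned.  The two-sided rule sums the probability
    of every table no more probable than the observed one (with the standard
    1 + 1e-7 tolerance).
    """
    table = np.asarray(table, dtype=int)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()
    obs = _log_table_prob(table, row_sums, col_sums, n)
    cutoff = obs + np.log1p(1e-7)
    try:
        total = 0.0
        for t in _enumerate_tables(list(row_sums), list(col_sums), enumeration_limit):
            arr = np.array(t)
            lp = _log_table_prob(arr, row_sums, col_sums, n)
            if lp <= cutoff:
                total += np.exp(lp)
        return float(min(1.0, total))
    except OverflowError:
        pass
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        remaining = col_sums.copy()
        lp = 0.0
        sim = np.empty_like(table)
        for i in range(table.shape[0] - 1):
            row = rng.multivariate_hypergeometric(remaining, row_sums[i])
            sim[i] = row
            remaining = remaining - row
        sim[-1] = remaining
        lp = _log_table_prob(sim, row_sums, col_sums, n)
        if lp <= cutoff:
            hits += 1
    return (1 + hits) / (1 + n_mc)
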