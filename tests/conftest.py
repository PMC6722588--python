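"""Shared fixtures and independent brute-force oracles.

The oracles here (exhaustive table enumeration, exhaustive partition
search, direct formula summations) are deliberately independent of the
package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from aroidnet.webs import InteractionWeb


@pytest.fixture(scope="session")
def survey_web():
    from aroidnet.datasets import survey_web

    return survey_web()


@pytest.fixture()
def toy_web():
    return InteractionWeb(np.array([[4, 2], [2, 1]]), ("a", "b"), ("x", "y"))


@pytest.fixture()
def diagonal_web():
    return InteractionWeb(np.array([[5, 0], [0, 5]]), ("a", "b"), ("x", "y"))


# ---------------------------------------------------------------------------
# oracles


def enumerate_tables(row_totals, col_totals):
    """Yield every non-negative integer table with the given marginals."""
    rows = list(row_totals)
    cols = list(col_totals)

    def rec(rows_left, cols_left):
        if len(rows_left) == 1:
            if all(x >= 0 for x in cols_left):
                yield (tuple(cols_left),)
            return
        t = rows_left[0]
        for combo in itertools.product(*[range(0, min(t, cl) + 1) for cl in cols_left]):
            if sum(combo) == t:
                rest = [cl - x for cl, x in zip(cols_left, combo)]
                for tail in rec(rows_left[1:], rest):
                    yield (combo,) + tail

    yield from rec(rows, cols)


def table_entropy(table) -> float:
    """Direct -sum p ln p with p = a/m over positive cells."""
    table = np.asarray(table, dtype=float)
    m = table.sum()
    h = 0.0
    for x in table.ravel():
        if x > 0:
            h -= (x / m) * math.log(x / m)
    return h


def exhaustive_q_max(web: InteractionWeb) -> float:
    """Global maximum of Barber's Q over all joint node partitions,
    by brute force over restricted-growth label strings."""
    n_rows, n_cols = web.shape
    n = n_rows + n_cols
    m = web.m
    k = web.row_totals
    d = web.col_totals
    B = web.counts - np.outer(k, d) / m

    best = -np.inf

    def rgs(prefix, maxlab):
        nonlocal best
        if len(prefix) == n:
            g = prefix[:n_rows]
            h = prefix[n_rows:]
            q = sum(
                B[i, j] for i in range(n_rows) for j in range(n_cols) if g[i] == h[j]
            ) / m
            best = max(best, q)
            return
        for lab in range(maxlab + 2):
            rgs(prefix + [lab], max(maxlab, lab))

    rgs([], -1)
    return float(best)


def hypergeometric_table_pmf(table, row_totals, col_totals) -> float:
    """Exact fixed-margins probability of one table:
    prod R_i! prod C_j! / (N! prod a_ij!)."""
    table = np.asarray(table)
    n = table.sum()
    num = 1.0
    for r in row_totals:
        num *= math.factorial(int(r))
    for c in col_totals:
        num *= math.factorial(int(c))
    den = math.factorial(int(n))
    for x in table.ravel():
        den *= math.factorial(int(x))
    return num / den
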