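"""Specialization, niche overlap and centrality for quantitative webs.

Implements the standardized two-dimensional Shannon specialization index
H2' of Bluethgen's framework, the species-level Kullback-Leibler host
selectivity index d', mean pairwise Morisita-Horn niche overlap, and
Kleinberg HITS hub/authority centrality on the log-transformed web.

All entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .webs import InteractionWeb, ValidationError

__all__ = [
    "ConvergenceError",
    "SpecializationResult",
    "CentralityResult",
    "shannon_h2",
    "h2_extrema",
    "h2prime",
    "dprime",
    "specialization",
    "morisita_horn",
    "mean_niche_overlap",
    "hits_scores",
]


class ConvergenceError(RuntimeError):
    """An iterative computation failed to reach its tolerance."""


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def shannon_h2(web: InteractionWeb) -> float:
    """Two-dimensional Shannon entropy H2 = -sum p_ij ln p_ij, p_ij = a_ij/m."""
    m = web.m
    if m <= 0:
        raise ValidationError("web has no interactions")
    p = web.counts / m
    return float(-_xlogx(p).sum())


def _entropy_of_table(table: np.ndarray, m: int) -> float:
    return float(-_xlogx(table / m).sum())


def _proportional_fill(row_totals: np.ndarray, col_totals: np.ndarray, ascent: bool) -> np.ndarray:
    """Near-proportional integer table with the given marginals.

    Starts from the floor of the expectation r_i c_j / m (whose partial
    sums never overshoot a marginal) and hands out the remaining units
    one at a time to a feasible cell — remaining row and column capacity
    both positive.  The target cell is the one furthest below its
    expectation, or with ``ascent`` the one with the largest marginal
    entropy gain (smallest current count, expectation deficit as the
    tie-break), a water-filling step that spreads units more evenly.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    m = int(r.sum())
    e = np.outer(r, c) / m
    a = np.floor(e).astype(np.int64)
    rr = r - a.sum(axis=1)
    cc = c - a.sum(axis=0)
    while rr.sum() > 0:
        rows = np.flatnonzero(rr > 0)
        cols = np.flatnonzero(cc > 0)
        deficit = (e - a)[np.ix_(rows, cols)]
        if ascent:
            sub_a = a[np.ix_(rows, cols)]
            # lexicographic: smallest count, then largest deficit
            key = -sub_a.astype(float) + deficit / (2.0 * m)
        else:
            key = deficit
        i, j = np.unravel_index(np.argmax(key), key.shape)
        a[rows[i], cols[j]] += 1
        rr[rows[i]] -= 1
        cc[cols[j]] -= 1
    return a


def _swap_ascent(a: np.ndarray, m: int, max_moves: int = 100_000) -> np.ndarray:
    """Greedy 2x2 cycle moves (marginal-preserving unit transfers) until
    no move increases the table entropy further.

    A move picks rows (i, i2) and columns (j, j2) and shifts one unit
    a[i,j]-1, a[i2,j]+1, a[i2,j2]-1, a[i,j2]+1; its entropy gain
    separates into per-cell decrement/increment terms, so the best move
    is found by a broadcast maximum over all (i, i2, j, j2).
    """

    def phi(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = -x[pos] * np.log(x[pos] / m)
        return out

    a = a.copy()
    for _ in range(max_moves):
        dec = np.where(a >= 1, phi(a - 1) - phi(a), -np.inf)  # remove one unit
        inc = phi(a + 1) - phi(a)  # add one unit
        # gain[i, i2, j, j2] = dec[i,j] + inc[i2,j] + dec[i2,j2] + inc[i,j2]
        part1 = dec[:, None, :] + inc[None, :, :]  # (i, i2, j)
        part2 = dec[None, :, :] + inc[:, None, :]  # (i, i2, j2)
        gain = part1[:, :, :, None] + part2[:, :, None, :]
        n_rows, n_cols = a.shape
        gain[np.arange(n_rows), np.arange(n_rows), :, :] = -np.inf
        gain[:, :, np.arange(n_cols), np.arange(n_cols)] = -np.inf
        idx = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[idx] <= 1e-12:
            return a
        i, i2, j, j2 = idx
        a[i, j] -= 1
        a[i2, j] += 1
        a[i2, j2] -= 1
        a[i, j2] += 1
    return a


def _fill_max_entropy(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Highest-entropy integer filling found by the proportional
    strategies, each refined by 2x2 cycle-move ascent."""
    m = int(np.sum(row_totals))
    candidates = [
        _swap_ascent(_proportional_fill(row_totals, col_totals, ascent=False), m),
        _swap_ascent(_proportional_fill(row_totals, col_totals, ascent=True), m),
    ]
    return max(candidates, key=lambda t: _entropy_of_table(t, m))


def _concentration_fill(row_totals: np.ndarray, col_totals: np.ndarray, match_equal: bool) -> np.ndarray:
    """Greedy concentration fill toward a low-entropy table.

    Repeatedly gives min(remaining row, remaining column) to the cell
    pairing the largest remaining marginals; with ``match_equal`` a pair
    of exactly equal marginals is consumed first (one saturated cell
    instead of two partial ones usually concentrates mass better).
    """
    r = np.asarray(row_totals, dtype=np.int64).copy()
    c = np.asarray(col_totals, dtype=np.int64).copy()
    a = np.zeros((r.size, c.size), dtype=np.int64)
    while r.sum() > 0:
        if match_equal:
            common = np.intersect1d(r[r > 0], c[c > 0])
            if common.size:
                v = int(common.max())
                i = int(np.flatnonzero(r == v)[0])
                j = int(np.flatnonzero(c == v)[0])
                a[i, j] += v
                r[i] -= v
                c[j] -= v
                continue
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        x = min(r[i], c[j])
        a[i, j] += x
        r[i] -= x
        c[j] -= x
    return a


def _fill_min_entropy(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Lowest-entropy integer filling found by the greedy strategies."""
    m = int(np.sum(row_totals))
    candidates = [
        _concentration_fill(row_totals, col_totals, match_equal=False),
        _concentration_fill(row_totals, col_totals, match_equal=True),
    ]
    return min(candidates, key=lambda t: _entropy_of_table(t, m))


def h2_extrema(row_totals, col_totals) -> tuple[float, float]:
    """Marginal-constrained bounds (H2min, H2max) of the web entropy.

    Computed from the concentration and proportional integer filling
    heuristics; used to standardize H2 into H2'.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if r.sum() != c.sum():
        raise ValidationError("row and column totals must share the same sum")
    if r.sum() <= 0:
        raise ValidationError("empty marginals")
    m = int(r.sum())
    h2min = _entropy_of_table(_fill_min_entropy(r, c), m)
    h2max = _entropy_of_table(_fill_max_entropy(r, c), m)
    if h2max < h2min:  # heuristics can cross only by float fuzz on tiny webs
        h2min, h2max = h2max, h2min
    return h2min, h2max


def h2prime(web: InteractionWeb) -> float:
    """Network-level standardized specialization H2' in [0, 1].

    H2' = (H2max - H2) / (H2max - H2min); 0 means interactions follow
    the marginal product (opportunistic), 1 maximal specialization given
    the marginals.  Degenerate webs with H2max = H2min return 0.
    """
    h2 = shannon_h2(web)
    h2min, h2max = h2_extrema(web.row_totals, web.col_totals)
    if h2max - h2min <= 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    pos = p > 0
    return float(np.sum(p[pos] * np.log(p[pos] / q[pos])))


def _d_max_fill(total: int, q: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Pack a species' total into the rarest resources first, capped by
    the resource marginals (ties by column order)."""
    out = np.zeros_like(caps)
    remaining = total
    for j in np.argsort(q, kind="stable"):
        if q[j] <= 0:
            continue
        x = min(remaining, int(caps[j]))
        out[j] = x
        remaining -= x
        if remaining == 0:
            break
    return out


def _d_prop_fill(total: int, q: np.ndarray) -> np.ndarray:
    """Closest-to-proportional integer allocation of a species total."""
    e = total * q
    out = np.floor(e).astype(np.int64)
    deficit = total - int(out.sum())
    order = np.argsort(-(e - out), kind="stable")
    k = 0
    while deficit > 0:
        j = order[k % order.size]
        if q[j] > 0:
            out[j] += 1
            deficit -= 1
        k += 1
    return out


def dprime(web: InteractionWeb, axis: str = "insects") -> pd.DataFrame:
    """Species-level selectivity d' for every species on one side.

    For insect i, d_i = sum_j p'_ij ln(p'_ij / q_j) with p'_ij = a_ij/A_i
    and q_j the host's share of all interactions; d' standardizes d_i by
    the integer marginal-feasible extremes (most-proportional filling for
    d_min, rarest-resource packing for d_max).

    Returns a DataFrame indexed by species with columns d, d_min, d_max,
    d_prime.
    """
    if axis == "insects":
        counts = web.counts
        labels = web.row_labels
    elif axis == "hosts":
        counts = web.counts.T
        labels = web.col_labels
    else:
        raise ValidationError(f"unknown axis {axis!r}; use 'insects' or 'hosts'")
    m = counts.sum()
    resource_totals = counts.sum(axis=0)
    q = resource_totals / m
    rows = []
    for i, lab in enumerate(labels):
        total = int(counts[i].sum())
        if total == 0:
            rows.append((lab, np.nan, np.nan, np.nan, np.nan))
            continue
        p = counts[i] / total
        d = _kl(p, q)
        dmax_vec = _d_max_fill(total, q, resource_totals)
        dmin_vec = _d_prop_fill(total, q)
        dmax = _kl(dmax_vec / total, q)
        dmin = _kl(dmin_vec / total, q)
        if dmax - dmin <= 1e-12:
            dp = 0.0
        else:
            dp = float(np.clip((d - dmin) / (dmax - dmin), 0.0, 1.0))
        rows.append((lab, d, dmin, dmax, dp))
    return pd.DataFrame(
        rows, columns=["species", "d", "d_min", "d_max", "d_prime"]
    ).set_index("species")


@dataclass(frozen=True)
class SpecializationResult:
    """Network- and species-level specialization of one web."""

    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float
    insect_dprime: pd.DataFrame
    host_dprime: pd.DataFrame


def specialization(web: InteractionWeb) -> SpecializationResult:
    """H2' plus per-species d' tables for both trophic levels."""
    h2 = shannon_h2(web)
    h2min, h2max = h2_extrema(web.row_totals, web.col_totals)
    return SpecializationResult(
        h2=h2,
        h2_min=h2min,
        h2_max=h2max,
        h2_prime=h2prime(web),
        insect_dprime=dprime(web, "insects"),
        host_dprime=dprime(web, "hosts"),
    )


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity of two abundance vectors, in [0, 1].

    1 for proportionally identical vectors, 0 for disjoint support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValidationError("abundance vectors must have positive totals")
    lam_x = np.sum(x * x) / (X * X)
    lam_y = np.sum(y * y) / (Y * Y)
    return float(2.0 * np.sum(x * y) / ((lam_x + lam_y) * X * Y))


def mean_niche_overlap(web: InteractionWeb, level: str = "insects") -> float:
    """Unweighted mean Morisita-Horn similarity over all unordered pairs
    of species at one trophic level (rows for insects, columns for hosts)."""
    if level == "insects":
        vectors = web.counts
    elif level == "hosts":
        vectors = web.counts.T
    else:
        raise ValidationError(f"unknown level {level!r}")
    n = vectors.shape[0]
    if n < 2:
        raise ValidationError("niche overlap needs at least two species")
    sims = [
        morisita_horn(vectors[i], vectors[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(sims))


@dataclass(frozen=True)
class CentralityResult:
    """HITS scores: insects as hubs, hosts as authorities; max scaled to 1."""

    hub: pd.Series
    authority: pd.Series
    n_iter: int
    residual: float


def hits_scores(
    web: InteractionWeb,
    transform: str = "log10",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> CentralityResult:
    """Kleinberg hub/authority centrality of the bipartite web.

    Power iteration on the weight matrix W (insects x hosts) obtained by
    the ``log10(x) + 1`` transform of positive counts (``transform="raw"``
    skips it): authority = W'h, hub = W a, renormalized each step from a
    uniform positive start.  Converged vectors are rescaled so the top
    score on each side is exactly 1.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    counts = web.counts.astype(float)
    if transform == "log10":
        W = np.zeros_like(counts)
        pos = counts > 0
        W[pos] = np.log10(counts[pos]) + 1.0
    elif transform == "raw":
        W = counts
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    h = np.ones(W.shape[0])
    h /= np.linalg.norm(h)
    a = np.zeros(W.shape[1])
    residual = np.inf
    for it in range(1, max_iter + 1):
        a_new = W.T @ h
        na = np.linalg.norm(a_new)
        if na == 0:
            raise ConvergenceError("web has no positive weights")
        a_new /= na
        h_new = W @ a_new
        h_new /= np.linalg.norm(h_new)
        residual = max(
            float(np.max(np.abs(h_new - h))), float(np.max(np.abs(a_new - a)))
        )
        h, a = h_new, a_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"HITS did not converge in {max_iter} iterations (residual {residual:.2e})"
        )
    h = h / h.max()
    a = a / a.max()
    return CentralityResult(
        hub=pd.Series(h, index=list(web.row_labels), name="hub"),
        authority=pd.Series(a, index=list(web.col_labels), name="authority"),
        n_iter=it,
        residual=residual,
    )
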