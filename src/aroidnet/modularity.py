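"""Weighted bipartite modularity and its label-propagation maximizer.

Barber's bipartite modularity compares within-module interaction weight
against the marginal-product expectation,

    Q = (1/m) sum_ij [a_ij - k_i d_j / m] delta(g_i, h_j),

with k_i the insect (row) totals and d_j the host (column) totals.  Q is
maximized by weighted label propagation (LPAwb+): row nodes start in
singleton modules, rows and columns alternately adopt the label with the
largest modularity gain, and converged partitions are refined by greedy
module merges.  The repeated-restart wrapper (DIRTLPAwb+ style) reruns
the propagation from randomized and coarse-grained initializations and
keeps the best partition found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .webs import InteractionWeb, ValidationError

__all__ = ["ModulePartition", "barber_modularity", "lpawb_plus", "dirt_lpawb_plus"]


@dataclass(frozen=True)
class ModulePartition:
    """A joint module labelling of both trophic levels with its Q."""

    row_modules: np.ndarray
    col_modules: np.ndarray
    q: float
    n_modules: int
    seed: int | None = None

    def as_dict(self, web: InteractionWeb) -> dict[str, int]:
        out = {l: int(g) for l, g in zip(web.row_labels, self.row_modules)}
        out.update({l: int(g) for l, g in zip(web.col_labels, self.col_modules)})
        return out


def _null_corrected(web: InteractionWeb) -> np.ndarray:
    m = web.m
    if m <= 0:
        raise ValidationError("web has no interactions")
    return web.counts - np.outer(web.row_totals, web.col_totals) / m


def barber_modularity(web: InteractionWeb, row_modules, col_modules) -> float:
    """Barber's Q for a given partition; 0 when all nodes share one module."""
    g = np.asarray(row_modules)
    h = np.asarray(col_modules)
    if g.size != web.shape[0] or h.size != web.shape[1]:
        raise ValidationError("module label vectors do not match the web shape")
    B = _null_corrected(web)
    return float(B[g[:, None] == h[None, :]].sum() / web.m)


def _relabel(g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Map labels to consecutive ids in order of first appearance (rows first)."""
    mapping: dict[int, int] = {}
    for lab in list(g) + list(h):
        if lab not in mapping:
            mapping[lab] = len(mapping)
    g2 = np.array([mapping[x] for x in g], dtype=np.int64)
    h2 = np.array([mapping[x] for x in h], dtype=np.int64)
    return g2, h2, len(mapping)


def _best_labels(B_side: np.ndarray, other_labels: np.ndarray) -> np.ndarray:
    """For each node (rows of B_side), the label among ``other_labels``
    with the largest summed null-corrected weight; ties to lowest label."""
    labels = np.unique(other_labels)  # sorted: argmax returns lowest on ties
    # score[n, l] = sum of B_side[n, k] over nodes k with other_labels == labels[l]
    onehot = (other_labels[:, None] == labels[None, :]).astype(float)
    scores = B_side @ onehot
    return labels[np.argmax(scores, axis=1)]


def _merge_pass(B: np.ndarray, g: np.ndarray, h: np.ndarray, m: int) -> bool:
    """Apply the single best Q-increasing merge of two modules, if any."""
    labels = np.unique(np.concatenate([g, h]))
    k = labels.size
    if k < 2:
        return False
    # gain(a,b) = (1/m) * [sum_{i in a_rows, j in b_cols} B_ij + sym.]
    row_onehot = (g[:, None] == labels[None, :]).astype(float)
    col_onehot = (h[:, None] == labels[None, :]).astype(float)
    block = row_onehot.T @ B @ col_onehot  # module x module aggregated B
    gains = block + block.T
    np.fill_diagonal(gains, -np.inf)
    a, b = np.unravel_index(np.argmax(gains), gains.shape)
    if gains[a, b] <= 1e-12:
        return False
    keep, drop = sorted((labels[a], labels[b]))
    g[g == drop] = keep
    h[h == drop] = keep
    return True


def lpawb_plus(
    web: InteractionWeb,
    seed: int | None = None,
    init_row_modules: np.ndarray | None = None,
    max_sweeps: int = 1000,
) -> ModulePartition:
    """One run of weighted bipartite label propagation (LPAwb+).

    Rows start in singleton modules (or ``init_row_modules``); columns
    then rows repeatedly adopt the best label until Q stops increasing,
    after which greedy module merges are attempted.  Deterministic: ties
    break toward the lowest module id and sweeps run in index order.
    """
    n_rows, n_cols = web.shape
    B = _null_corrected(web)
    m = web.m
    if init_row_modules is None:
        g = np.arange(n_rows, dtype=np.int64)
    else:
        g = np.asarray(init_row_modules, dtype=np.int64).copy()
        if g.size != n_rows:
            raise ValidationError("init_row_modules length mismatch")
    h = _best_labels(B.T, g)
    q = barber_modularity(web, g, h)
    for _ in range(max_sweeps):
        h_new = _best_labels(B.T, g)
        g_new = _best_labels(B, h_new)
        q_new = barber_modularity(web, g_new, h_new)
        if q_new > q + 1e-12:
            g, h, q = g_new, h_new, q_new
            continue
        if not _merge_pass(B, g, h, m):
            break
        q = barber_modularity(web, g, h)
    g, h, n_modules = _relabel(g, h)
    return ModulePartition(g, h, barber_modularity(web, g, h), n_modules, seed)


def dirt_lpawb_plus(
    web: InteractionWeb, n_restarts: int = 20, seed: int = 0
) -> ModulePartition:
    """Repeated-restart label propagation; returns the best-Q partition.

    The restart schedule mixes (a) the deterministic singleton start,
    (b) uniform-random row labelings, and (c) coarse starts that divide
    the rows into c initial modules for c = 2 .. min(web dimensions).
    Reproducible given ``seed``.
    """
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = web.shape
    best = lpawb_plus(web, seed=seed)
    schedules: list[np.ndarray] = []
    c_values = list(range(2, max(2, min(n_rows, n_cols)) + 1))
    for k in range(n_restarts - 1):
        if k % 2 == 0 and c_values:
            c = c_values[(k // 2) % len(c_values)]
            init = rng.integers(0, c, size=n_rows)
        else:
            init = rng.integers(0, n_rows, size=n_rows)
        schedules.append(init.astype(np.int64))
    for init in schedules:
        cand = lpawb_plus(web, seed=seed, init_row_modules=init)
        if cand.q > best.q + 1e-12:
            best = cand
    return ModulePartition(best.row_modules, best.col_modules, best.q, best.n_modules, seed)
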