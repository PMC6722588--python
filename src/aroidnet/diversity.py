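"""Richness estimation and abundance-based beta-diversity partitioning.

Covers sample-based species accumulation, the first-order jackknife
richness estimator over sampling units (infructescences), sampling
completeness, and Baselga's decomposition of Bray-Curtis dissimilarity
into balanced-variation and abundance-gradient components, in both
pairwise and multi-site forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .webs import RecordTable, ValidationError

__all__ = [
    "RichnessEstimate",
    "BetaDecomposition",
    "accumulation_curve",
    "jackknife1",
    "completeness",
    "bray_curtis_partition",
    "multi_site_bray",
]


@dataclass(frozen=True)
class RichnessEstimate:
    """Observed vs first-order-jackknife expected species richness."""

    s_obs: int
    q1: int
    n_units: int
    s_jack1: float
    completeness: float  # percent, 100 * S_obs / S_jack1
    variant: str


@dataclass(frozen=True)
class BetaDecomposition:
    """Bray-Curtis dissimilarity split into its two abundance components.

    ``balanced`` captures balanced variation (some species decline as
    others increase by the same magnitude), ``gradient`` uniform
    increase/decline of all species; the two add up to ``total``.
    """

    total: float
    balanced: float
    gradient: float


def completeness(s_obs: float, s_expected: float) -> float:
    """Sampling completeness in percent: 100 * S_obs / S_expected."""
    if s_expected <= 0:
        raise ValidationError("expected richness must be positive")
    return 100.0 * s_obs / s_expected


def jackknife1(records: RecordTable, variant: str = "incidence") -> RichnessEstimate:
    """First-order jackknife richness over sampling units.

    ``variant="incidence"`` (default) counts Q1 = species occurring in
    exactly one sampling unit; ``variant="abundance"`` uses f1 = species
    represented by exactly one individual.  Either way,

        S_jack1 = S_obs + Q1 * (m - 1) / m,

    with m the number of sampling units.
    """
    mat = records.unit_matrix()
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    m = mat.shape[0]
    if m < 2:
        raise ValidationError("jackknife needs at least two sampling units")
    s_obs = mat.shape[1]
    if variant == "incidence":
        q1 = int(((mat > 0).sum(axis=0) == 1).sum())
    elif variant == "abundance":
        q1 = int((mat.sum(axis=0) == 1).sum())
    else:
        raise ValidationError(f"unknown jackknife variant {variant!r}")
    s_jack1 = s_obs + q1 * (m - 1) / m
    return RichnessEstimate(
        s_obs=s_obs,
        q1=q1,
        n_units=m,
        s_jack1=float(s_jack1),
        completeness=completeness(s_obs, s_jack1),
        variant=variant,
    )


def accumulation_curve(
    records: RecordTable, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Sample-based species accumulation: mean +/- sd richness vs units.

    Averages cumulative richness over ``n_perm`` random orderings of the
    sampling units; the curve is monotone non-decreasing and its final
    point equals the pooled observed richness.
    """
    mat = (records.unit_matrix() > 0).to_numpy()
    m, s = mat.shape
    if m < 1:
        raise ValidationError("no sampling units")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, m), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(m)
        seen = np.cumsum(mat[order], axis=0) > 0
        curves[p] = seen.sum(axis=1)
    return pd.DataFrame(
        {
            "k": np.arange(1, m + 1),
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(m),
        }
    )


def _abc(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a = float(np.minimum(x, y).sum())
    b = float(x.sum() - a)
    c = float(y.sum() - a)
    return a, b, c


def bray_curtis_partition(x, y) -> BetaDecomposition:
    """Pairwise Bray-Curtis dissimilarity and its Baselga decomposition.

    With A = sum_i min(x_i, y_i), B = sum x - A and C = sum y - A:

        d_BC      = (B + C) / (2A + B + C)
        balanced  = min(B, C) / (A + min(B, C))
        gradient  = d_BC - balanced
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("site vectors must have equal length")
    if x.sum() <= 0 and y.sum() <= 0:
        raise ValidationError("both sites empty")
    a, b, c = _abc(x, y)
    denom = 2 * a + b + c
    total = (b + c) / denom
    mn = min(b, c)
    balanced = mn / (a + mn) if (a + mn) > 0 else 0.0
    return BetaDecomposition(total=total, balanced=balanced, gradient=total - balanced)


def multi_site_bray(matrix) -> BetaDecomposition:
    """Multi-site Bray-Curtis decomposition over all site pairs.

    ``matrix`` is sites (rows) x species (columns).  Components use sums
    over all unordered site pairs:

        balanced = sum min(B,C) / (sum A + sum min(B,C))
        total    = (sum B + sum C) / (2 sum A + sum B + sum C)
        gradient = total - balanced
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValidationError("need a sites x species matrix with >= 2 sites")
    if np.any(mat.sum(axis=1) <= 0):
        raise ValidationError("every site needs a positive total abundance")
    sum_a = sum_b = sum_c = sum_min = 0.0
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = _abc(mat[i], mat[j])
            sum_a += a
            sum_b += b
            sum_c += c
            sum_min += min(b, c)
    total = (sum_b + sum_c) / (2 * sum_a + sum_b + sum_c)
    balanced = sum_min / (sum_a + sum_min) if (sum_a + sum_min) > 0 else 0.0
    return BetaDecomposition(total=total, balanced=balanced, gradient=total - balanced)
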