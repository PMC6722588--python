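"""Fixed-marginal (Patefield) null model and null-ensemble significance.

The null model draws contingency tables uniformly from the multivariate
hypergeometric law conditioned on both marginal totals, by filling the
table cell-by-cell with sequential conditional hypergeometric draws.
Any scalar web statistic can be evaluated over an ensemble of such
draws; significance is summarized by the Z-score against the null
distribution (Z >= 2 conventionally "highly significant") and by an
empirical p-value using the (1 + b)/(1 + n) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .webs import InteractionWeb, ValidationError
from . import metrics as _metrics
from . import modularity as _modularity

__all__ = ["NullEnsemble", "patefield_sample", "null_ensemble", "make_statistic"]


def patefield_sample(row_totals, col_totals, rng: np.random.Generator) -> np.ndarray:
    """One random integer table with exactly the given marginals.

    Cells are filled row by row; each cell is a hypergeometric draw
    conditioned on the remaining row and column totals, which yields the
    classic fixed-margins (multiple hypergeometric) law.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if np.any(r < 0) or np.any(c < 0):
        raise ValidationError("marginals must be non-negative")
    if r.sum() != c.sum():
        raise ValidationError("row and column totals must share the same sum")
    out = np.zeros((r.size, c.size), dtype=np.int64)
    c_left = c.copy()
    for i in range(r.size):
        row_left = int(r[i])
        total_left = int(c_left.sum())
        for j in range(c.size - 1):
            if row_left == 0:
                break
            good = int(c_left[j])
            x = int(rng.hypergeometric(good, total_left - good, row_left)) if good else 0
            out[i, j] = x
            row_left -= x
            total_left -= good
        out[i, -1] = row_left
        c_left -= out[i]
    return out


@dataclass(frozen=True)
class NullEnsemble:
    """Observed statistic with its fixed-marginal null distribution."""

    statistic: str
    observed: float
    null_values: np.ndarray
    z: float  # nan when the null distribution is degenerate
    z_defined: bool
    p_value: float
    tail: str
    n: int
    seed: int

    @property
    def significant(self) -> bool:
        """The Z >= 2 high-significance convention (two-sided: |Z| >= 2)."""
        return self.z_defined and abs(self.z) >= 2.0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))


def make_statistic(name: str, **kwargs) -> Callable[[InteractionWeb], float]:
    """Resolve a statistic by name: H2prime, NO, Q, H2.

    ``Q`` accepts ``n_restarts`` and ``seed`` keyword arguments for its
    internal restart schedule.
    """
    key = name.lower()
    if key in {"h2prime", "h2'"}:
        return _metrics.h2prime
    if key == "h2":
        return _metrics.shannon_h2
    if key in {"no", "niche_overlap"}:
        level = kwargs.get("level", "insects")
        return lambda web: _metrics.mean_niche_overlap(web, level)
    if key in {"q", "modularity"}:
        n_restarts = kwargs.get("n_restarts", 5)
        seed = kwargs.get("seed", 0)
        return lambda web: _modularity.dirt_lpawb_plus(web, n_restarts, seed).q
    raise KeyError(f"unknown statistic {name!r}")


def null_ensemble(
    web: InteractionWeb,
    statistic: str | Callable[[InteractionWeb], float],
    n: int = 100,
    seed: int = 0,
    tail: str = "two-sided",
    **statistic_kwargs,
) -> NullEnsemble:
    """Evaluate a statistic on ``n`` Patefield draws from the web's marginals.

    The empirical p-value is (1 + b) / (1 + n) with b the number of null
    values at least as extreme as the observed one in the requested tail
    (``"greater"``, ``"less"``, or ``"two-sided"`` which doubles the
    smaller one-sided estimate, capped at 1).  A conserved statistic
    (zero null spread) yields ``z_defined=False`` rather than an error.
    """
    if tail not in {"greater", "less", "two-sided"}:
        raise ValidationError(f"unknown tail {tail!r}")
    func = make_statistic(statistic, **statistic_kwargs) if isinstance(statistic, str) else statistic
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "statistic")
    rng = np.random.default_rng(seed)
    observed = float(func(web))
    nulls = np.empty(n, dtype=float)
    for k in range(n):
        table = patefield_sample(web.row_totals, web.col_totals, rng)
        nulls[k] = float(func(InteractionWeb(table, web.row_labels, web.col_labels)))
    sd = float(np.std(nulls, ddof=1)) if n > 1 else 0.0
    if sd > 0:
        z = float((observed - np.mean(nulls)) / sd)
        z_defined = True
    else:
        z = float("nan")
        z_defined = False
    b_hi = int(np.sum(nulls >= observed))
    b_lo = int(np.sum(nulls <= observed))
    if tail == "greater":
        p = (1 + b_hi) / (1 + n)
    elif tail == "less":
        p = (1 + b_lo) / (1 + n)
    else:
        p = min(1.0, 2.0 * (1 + min(b_hi, b_lo)) / (1 + n))
    return NullEnsemble(
        statistic=str(name),
        observed=observed,
        null_values=nulls,
        z=z,
        z_defined=z_defined,
        p_value=float(p),
        tail=tail,
        n=n,
        seed=seed,
    )
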