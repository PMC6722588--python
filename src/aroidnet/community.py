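"""Frequency/abundance dominance index and guild contingency testing.

The frequency/abundance index (IFA) ranks insect species within a host
by combining how many of the host's infructescences they occupy with
their numerical share of the host's individuals:

    IFA = rf * ra * 100,

rf the proportion of sampled infructescences occupied and ra the
proportion of individuals.  Guild composition across hosts is tested
with a log-likelihood-ratio (G) test of independence using the Williams
small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .webs import GuildMap, InteractionWeb, RecordTable, ValidationError

__all__ = [
    "GTestResult",
    "ifa_score",
    "ifa_table",
    "guild_abundance_table",
    "williams_g_test",
]


def ifa_score(rf: float, ra: float) -> float:
    """IFA = rf * ra * 100, both inputs as proportions in [0, 1]."""
    if not (0 <= rf <= 1 and 0 <= ra <= 1):
        raise ValidationError("rf and ra must be proportions in [0, 1]")
    return rf * ra * 100.0


def ifa_table(records: RecordTable, host: str) -> pd.DataFrame:
    """Per-species rf, ra and IFA for one host, sorted by IFA descending.

    rf = occupied sampling units / sampled units of the host;
    ra = species individuals / all individuals reared from the host.
    """
    if host not in set(records.frame["host"]):
        raise KeyError(f"unknown host {host!r}")
    mat = records.unit_matrix(host)
    n_units = mat.shape[0]
    total = mat.to_numpy().sum()
    if n_units < 1 or total <= 0:
        raise ValidationError(f"host {host!r} has no occupied sampling units")
    rf = (mat > 0).sum(axis=0) / n_units
    ra = mat.sum(axis=0) / total
    out = pd.DataFrame({"host": host, "rf": rf, "ra": ra})
    out = out[out["ra"] > 0]
    out["ifa"] = out["rf"] * out["ra"] * 100.0
    out.index.name = "species"
    return out.sort_values("ifa", ascending=False)


def guild_abundance_table(web: InteractionWeb, guilds: GuildMap) -> pd.DataFrame:
    """Aggregate an insect x host web into a guild x host count table."""
    guilds.require(web.row_labels)
    frame = web.to_frame()
    frame["guild"] = [guilds[s] for s in web.row_labels]
    table = frame.groupby("guild").sum()
    order = [g for g in ("P", "P-S", "S", "M") if g in table.index]
    return table.loc[order]


@dataclass(frozen=True)
class GTestResult:
    """Williams-corrected G-test of independence for an r x c table."""

    g: float
    q: float  # Williams correction factor, >= 1
    g_adj: float
    df: int
    p_value: float


def williams_g_test(table) -> GTestResult:
    """G-test of independence with the Williams correction.

    G = 2 sum O ln(O/E) with E the usual independence expectation;
    zero cells contribute nothing.  The correction factor is

        q = 1 + (N sum 1/R_i - 1)(N sum 1/C_j - 1) / (6 N (r-1)(c-1)),

    and the p-value is the chi-square upper tail of G/q at
    df = (r-1)(c-1).  Rows or columns with zero totals must be dropped
    before testing.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValidationError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValidationError("negative cell count")
    R = obs.sum(axis=1)
    C = obs.sum(axis=0)
    if np.any(R == 0) or np.any(C == 0):
        raise ValidationError("zero row/column marginal; collapse the table first")
    N = obs.sum()
    E = np.outer(R, C) / N
    pos = obs > 0
    g = float(2.0 * np.sum(obs[pos] * np.log(obs[pos] / E[pos])))
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    q = 1.0 + (N * np.sum(1.0 / R) - 1.0) * (N * np.sum(1.0 / C) - 1.0) / (6.0 * N * df)
    g_adj = g / q
    return GTestResult(g=g, q=float(q), g_adj=float(g_adj), df=df, p_value=float(chi2.sf(g_adj, df)))
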