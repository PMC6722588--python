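"""Curated fixtures from the Los Tuxtlas aroid-insect survey.

Three tables from the published survey of endophagous insects reared
from infructescences of eight aroid species at three elevations in the
Los Tuxtlas Biosphere Reserve (Veracruz, Mexico) ship with the package:

``infructescences``
    Sampling effort: infructescences collected per host and elevation
    (250 units in total).
``abundance_pct``
    34 insect species x 8 hosts, the percentage of each host's
    individuals contributed by each species, with exact per-species
    specimen totals (16,120 individuals) and trophic-guild labels.
``ifa``
    Per-host relative frequency, relative abundance and the resulting
    frequency/abundance index (IFA) for the dominant species.

The integer interaction web behind the percentage table is not printed
anywhere; :func:`survey_web` reconstructs it by solving for host column
totals and rounding by largest remainder (see
:func:`aroidnet.webs.reconstruct_counts`).

The printed tables carry small internal discrepancies (the sampling
table reports 77 *D. oerstedii* infructescences where the IFA table uses
73, and 19 vs 9 for *R. wendlandii*); each fixture reproduces its own
table as printed and no reconciliation is attempted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .webs import GuildMap, InteractionWeb, PercentageTable, reconstruct_counts

__all__ = [
    "load_infructescence_summary",
    "load_abundance_percentages",
    "load_ifa_reference",
    "load_guilds",
    "load_fixture",
    "survey_web",
    "survey_ifa_table",
]

_ALIASES = {
    "table1": "infructescences",
    "infructescences": "infructescences",
    "table2": "abundance_pct",
    "abundance_pct": "abundance_pct",
    "abundance": "abundance_pct",
    "table5": "ifa",
    "ifa": "ifa",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("aroidnet.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@lru_cache(maxsize=None)
def load_infructescence_summary() -> pd.DataFrame:
    """Infructescences sampled per host (rows) and elevation site (columns).

    Sites are ordered low to high: BSLT, La Perla, Caleria.  The ``total``
    column is the printed per-host total; the grand total is 250.
    """
    frame = _read("tuxtlas_infructescences.csv").set_index("host")
    sites = ["BSLT", "La Perla", "Caleria"]
    if not (frame[sites].sum(axis=1) == frame["total"]).all():
        raise AssertionError("fixture corrupted: host totals do not add up")
    return frame


@lru_cache(maxsize=None)
def load_abundance_percentages() -> PercentageTable:
    """The 34 x 8 per-host percentage-abundance table with exact row totals."""
    frame = _read("tuxtlas_abundance_pct.csv")
    hosts = [c for c in frame.columns if c not in {"family", "species", "code", "guild", "total"}]
    pct = frame.set_index("code")[hosts]
    totals = frame.set_index("code")["total"]
    return PercentageTable(pct, totals, int(totals.sum()))


@lru_cache(maxsize=None)
def load_guilds() -> GuildMap:
    """Trophic-guild label for each insect species code."""
    frame = _read("tuxtlas_abundance_pct.csv")
    return GuildMap(dict(zip(frame["code"], frame["guild"])))


@lru_cache(maxsize=None)
def load_ifa_reference() -> pd.DataFrame:
    """Printed per-host IFA table: host, sampled units, species, rf, ra, IFA."""
    return _read("tuxtlas_ifa.csv")


def load_fixture(name: str):
    """Load a survey fixture by name.

    Accepted names: ``infructescences``/``table1``, ``abundance_pct``/
    ``table2``, ``ifa``/``table5``.
    """
    try:
        canonical = _ALIASES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of {sorted(set(_ALIASES))}"
        ) from None
    if canonical == "infructescences":
        return load_infructescence_summary()
    if canonical == "abundance_pct":
        return load_abundance_percentages()
    return load_ifa_reference()


@lru_cache(maxsize=None)
def survey_web() -> InteractionWeb:
    """The reconstructed 34-insect x 8-host integer interaction web.

    Row sums equal the printed specimen totals exactly and the grand
    total is 16,120 individuals; host column totals are inferred by
    constrained non-negative least squares.
    """
    return reconstruct_counts(load_abundance_percentages())


def survey_ifa_table() -> pd.DataFrame:
    """IFA recomputed from the printed inputs: rf from the IFA table,
    relative abundance from the percentage-abundance table.

    Returns the reference table with an ``ifa_recomputed`` column
    (rf x ra x 100, ra taken at the percentage table's two-decimal
    precision).  This is the printed-data path; with raw per-unit
    records available use :func:`aroidnet.community.ifa_table` instead.
    """
    ref = load_ifa_reference().copy()
    pct = load_abundance_percentages().pct
    ra = [pct.at[sp, host] / 100.0 for sp, host in zip(ref["species"], ref["host"])]
    ref["ra_from_pct"] = ra
    ref["ifa_recomputed"] = ref["rf"] * ref["ra_from_pct"] * 100.0
    return ref
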