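"""Core containers for quantitative bipartite interaction data.

The central object is :class:`InteractionWeb`, an integer count matrix of
consumer species (rows, here endophagous insects) by resource species
(columns, here aroid host plants).  Per-sampling-unit occurrence data —
one infructescence is one sampling unit — live in :class:`RecordTable`
and aggregate losslessly into a web.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "FormatError",
    "ValidationError",
    "ReconstructionError",
    "InteractionWeb",
    "RecordTable",
    "GuildMap",
    "PercentageTable",
    "read_web",
    "write_web",
    "read_records",
    "write_records",
    "percentage_table",
    "reconstruct_counts",
    "GUILDS",
]

GUILDS = ("P", "S", "M", "P-S")

RECORD_COLUMNS = ["host", "elevation", "unit_id", "species", "count"]


class FormatError(ValueError):
    """A delimited file does not have the expected layout."""


class ValidationError(ValueError):
    """Data violate an invariant of the container being built."""


class ReconstructionError(RuntimeError):
    """No feasible integer web is consistent with a percentage table."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate {what} labels")
    return labels


@dataclass(frozen=True, eq=False)
class InteractionWeb:
    """Integer interaction counts, insects (rows) x hosts (columns).

    Parameters
    ----------
    counts
        Non-negative integer matrix; cell (i, j) is the number of
        individuals of insect i reared from host j.
    row_labels, col_labels
        Unique species codes for rows (insects) and columns (hosts).
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.size == 0:
            raise ValidationError("counts must be a non-empty 2-D matrix")
        if not np.issubdtype(counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(counts < 0):
            raise ValidationError("negative interaction count")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("non-integer interaction count")
        counts = np.round(counts).astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        rows = _check_unique(self.row_labels, "row")
        cols = _check_unique(self.col_labels, "column")
        if len(rows) != counts.shape[0] or len(cols) != counts.shape[1]:
            raise ValidationError("label length does not match matrix shape")
        object.__setattr__(self, "row_labels", tuple(rows))
        object.__setattr__(self, "col_labels", tuple(cols))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionWeb):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:
        return hash((self.row_labels, self.col_labels, self.counts.tobytes()))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def m(self) -> int:
        """Grand total number of interaction events (individuals)."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def trim(self) -> "InteractionWeb":
        """Drop all-zero rows and columns (species with no interactions)."""
        rk = self.row_totals > 0
        ck = self.col_totals > 0
        if not rk.any() or not ck.any():
            raise ValidationError("web is empty after trimming")
        return InteractionWeb(
            self.counts[np.ix_(rk, ck)],
            tuple(l for l, k in zip(self.row_labels, rk) if k),
            tuple(l for l, k in zip(self.col_labels, ck) if k),
        )

    def transpose(self) -> "InteractionWeb":
        return InteractionWeb(self.counts.T, self.col_labels, self.row_labels)

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.row_labels.index(label)]

    def col(self, label: str) -> np.ndarray:
        return self.counts[:, self.col_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionWeb":
        return cls(frame.to_numpy(), tuple(map(str, frame.index)), tuple(map(str, frame.columns)))


@dataclass(frozen=True)
class RecordTable:
    """Long-format per-infructescence occurrence records.

    Columns: host, elevation, unit_id, species, count.  A sampling unit
    is identified by the (host, unit_id) pair; aggregating counts over
    units reproduces an :class:`InteractionWeb`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"record table missing columns {missing}")
        frame = frame[RECORD_COLUMNS].copy()
        counts = pd.to_numeric(frame["count"], errors="coerce")
        if counts.isna().any():
            raise ValidationError("non-numeric count in record table")
        if (counts < 0).any():
            raise ValidationError("negative count in record table")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("non-integer count in record table")
        frame["count"] = counts.round().astype(np.int64)
        for c in ("host", "elevation", "unit_id", "species"):
            frame[c] = frame[c].astype(str)
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def hosts(self) -> list[str]:
        return sorted(self.frame["host"].unique())

    @property
    def elevations(self) -> list[str]:
        return sorted(self.frame["elevation"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def units(self, host: str | None = None) -> pd.DataFrame:
        """Distinct sampling units as (host, unit_id) pairs."""
        f = self.frame if host is None else self.frame[self.frame["host"] == host]
        return f[["host", "unit_id"]].drop_duplicates().reset_index(drop=True)

    def subset(self, *, host: str | None = None, elevation: str | None = None) -> "RecordTable":
        f = self.frame
        if host is not None:
            f = f[f["host"] == host]
        if elevation is not None:
            f = f[f["elevation"] == elevation]
        if f.empty:
            raise ValidationError("subset selects no records")
        return RecordTable(f)

    def to_web(self, trim: bool = True) -> InteractionWeb:
        """Aggregate counts over sampling units into a species x host web."""
        pivot = self.frame.pivot_table(
            index="species", columns="host", values="count", aggfunc="sum", fill_value=0
        ).sort_index(axis=0).sort_index(axis=1)
        web = InteractionWeb.from_frame(pivot)
        return web.trim() if trim else web

    def unit_matrix(self, host: str | None = None) -> pd.DataFrame:
        """Sampling units (rows) x species (columns) abundance matrix."""
        f = self.frame if host is None else self.frame[self.frame["host"] == host]
        if f.empty:
            raise ValidationError("no records for requested host")
        f = f.assign(unit=f["host"] + "::" + f["unit_id"])
        return f.pivot_table(
            index="unit", columns="species", values="count", aggfunc="sum", fill_value=0
        ).sort_index(axis=0).sort_index(axis=1)


class GuildMap(Mapping[str, str]):
    """Mapping from insect species code to trophic guild.

    Guilds: ``P`` phytophagous, ``S`` saprophagous, ``M`` mycetophagous,
    ``P-S`` mixed phytophagous-saprophagous.
    """

    def __init__(self, mapping: Mapping[str, str]):
        bad = {s: g for s, g in mapping.items() if g not in GUILDS}
        if bad:
            raise ValidationError(f"unknown guilds {bad}; expected one of {GUILDS}")
        self._map = {str(s): g for s, g in mapping.items()}

    def __getitem__(self, key: str) -> str:
        return self._map[key]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def require(self, species: Iterable[str]) -> None:
        missing = [s for s in species if s not in self._map]
        if missing:
            raise ValidationError(f"species without guild assignment: {missing}")


@dataclass(frozen=True)
class PercentageTable:
    """Column-wise percentage presentation of a web plus exact row totals.

    ``pct`` holds, for each host column, the percentage of that host's
    individuals belonging to each insect species; ``row_totals`` are the
    exact per-species specimen totals and ``grand_total`` their sum.
    """

    pct: pd.DataFrame
    row_totals: pd.Series
    grand_total: int
    column_sum_tol: float = field(default=0.5, compare=False)

    def __post_init__(self) -> None:
        pct = self.pct.astype(float)
        if ((pct < 0) | (pct > 100)).any().any():
            raise ValidationError("percentages must lie in [0, 100]")
        colsums = pct.sum(axis=0)
        nonzero = colsums[colsums > 0]
        off = (nonzero - 100.0).abs()
        if (off > self.column_sum_tol).any():
            raise ValidationError(
                f"non-zero columns must sum to 100 +/- {self.column_sum_tol}: {dict(off[off > self.column_sum_tol])}"
            )
        totals = self.row_totals.reindex(pct.index)
        if totals.isna().any():
            raise ValidationError("row_totals must cover every species in pct")
        if int(totals.sum()) != int(self.grand_total):
            raise ValidationError(
                f"row totals sum to {int(totals.sum())}, expected grand total {self.grand_total}"
            )
        object.__setattr__(self, "pct", pct)
        object.__setattr__(self, "row_totals", totals.astype(np.int64))
        object.__setattr__(self, "grand_total", int(self.grand_total))


# ---------------------------------------------------------------------------
# delimited-file IO


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_web(path: str | Path, orientation: str = "insects-rows", allow_rounding: bool = False) -> InteractionWeb:
    """Read a labelled count matrix from CSV/TSV.

    ``orientation`` is ``"insects-rows"`` (default) or ``"insects-cols"``
    (matrix transposed on read so that insects end up on rows).
    Non-integer cells are rejected unless ``allow_rounding`` is set.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise FormatError(f"{path} holds no data cells")
    values = frame.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise FormatError(f"{path} has non-numeric cells")
    if not allow_rounding and not np.allclose(values, np.round(values)):
        raise ValidationError(
            "non-integer cells; pass allow_rounding=True to round on read"
        )
    frame = values.round().astype(np.int64)
    if orientation == "insects-cols":
        frame = frame.T
    elif orientation != "insects-rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return InteractionWeb.from_frame(frame)


def write_web(web: InteractionWeb, path: str | Path) -> None:
    path = Path(path)
    web.to_frame().to_csv(path, sep=_sep_for(path), lineterminator="\n")


def read_records(path: str | Path) -> RecordTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return RecordTable(frame)


def write_records(records: RecordTable, path: str | Path) -> None:
    path = Path(path)
    records.frame.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# reconstruction of integer counts from a percentage presentation


def percentage_table(web: InteractionWeb) -> PercentageTable:
    """Express a web as per-host column percentages at full precision."""
    ct = web.col_totals.astype(float)
    if np.any(ct == 0):
        raise ValidationError("percentage presentation undefined for empty columns")
    pct = pd.DataFrame(
        100.0 * web.counts / ct[None, :],
        index=list(web.row_labels),
        columns=list(web.col_labels),
    )
    totals = pd.Series(web.row_totals, index=list(web.row_labels))
    return PercentageTable(pct, totals, web.m)


def _largest_remainder_row(real_row: np.ndarray, target: int) -> np.ndarray:
    """Round a non-negative real row to integers summing exactly to target.

    Support is restricted to positive entries; remaining units go to the
    largest fractional remainders (ties broken by column order).
    """
    out = np.floor(real_row).astype(np.int64)
    out[real_row <= 0] = 0
    support = np.flatnonzero(real_row > 0)
    if target == 0:
        return np.zeros_like(out)
    if support.size == 0:
        raise ReconstructionError("positive row total but no positive cells")
    deficit = target - int(out.sum())
    if deficit < 0:  # floors already overshoot: pull from smallest remainders
        order = support[np.argsort(real_row[support] - out[support], kind="stable")]
        i = 0
        while deficit < 0:
            j = order[i % order.size]
            if out[j] > 0:
                out[j] -= 1
                deficit += 1
            i += 1
        return out
    remainders = real_row[support] - out[support]
    order = support[np.argsort(-remainders, kind="stable")]
    i = 0
    while deficit > 0:
        out[order[i % order.size]] += 1
        deficit -= 1
        i += 1
    return out


def reconstruct_counts(
    table: PercentageTable, max_abs_residual: float = 5.0
) -> InteractionWeb:
    """Invert a column-percentage table back to an integer count web.

    Solves for non-negative host (column) totals ``c_j`` minimising
    ``sum_i (sum_j pct_ij c_j / 100 - row_total_i)^2`` subject to
    ``sum_j c_j = grand_total`` (equality enforced by a penalty row and a
    final rescaling), then rounds each row by largest remainder so every
    species keeps its exact printed specimen total.

    Raises :class:`ReconstructionError` when the best non-negative
    solution leaves any species residual above ``max_abs_residual``
    individuals.
    """
    A = table.pct.to_numpy() / 100.0
    b = table.row_totals.to_numpy().astype(float)
    G = float(table.grand_total)
    # penalty row weight large relative to the data scale; solution rescaled after
    w = 1e6
    A_aug = np.vstack([A, w * np.ones((1, A.shape[1]))])
    b_aug = np.concatenate([b, [w * G]])
    c, _ = nnls(A_aug, b_aug)
    if c.sum() <= 0:
        raise ReconstructionError("degenerate solution: all column totals zero")
    c *= G / c.sum()
    residual = A @ c - b
    worst = float(np.max(np.abs(residual)))
    if worst > max_abs_residual:
        report = pd.Series(residual, index=table.pct.index)
        raise ReconstructionError(
            "no non-negative column totals reproduce the row totals within "
            f"{max_abs_residual} individuals; worst residual {worst:.2f}\n"
            f"{report[report.abs() > max_abs_residual]}"
        )
    real = A * c[None, :]
    counts = np.vstack(
        [
            _largest_remainder_row(real[i], int(b[i]))
            for i in range(real.shape[0])
        ]
    )
    return InteractionWeb(
        counts, tuple(table.pct.index.map(str)), tuple(table.pct.columns.map(str))
    )
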