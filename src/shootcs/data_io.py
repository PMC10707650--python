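"""Reading, filtering and summarising shoot-concentration sample tables.

The on-disk format is a flat CSV with one row per sampled individual:
stand label, species name, stem origin (0 = coppice sprout, 1 = plantation),
measured radiocesium activity concentration in Bq kg^-1, and a flag marking
records below the detection limit.  Below-detection ("censored") records are
excluded from all model fitting because their detection limits vary with
counting time; :func:`exclude_censored` performs that filter and reports the
excluded fraction.

Column names are remappable because supplementary data files in this area do
not share a fixed header convention.  Any record whose activity cell is
missing, non-positive, or whose censored flag is truthy is treated as
censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "SampleTable",
    "StandSummary",
    "SchemaError",
    "ParseError",
    "EmptyAnalysisError",
    "read_samples",
    "write_samples",
    "exclude_censored",
    "stand_summaries",
    "summaries_frame",
    "flag_outliers",
]

DEFAULT_COLUMNS: dict[str, str] = {
    "stand": "stand",
    "species": "species",
    "origin": "origin",
    "activity": "activity",
    "censored": "censored",
}

_ORIGIN_ALIASES = {
    "0": 0, "sprout": 0, "coppice": 0,
    "1": 1, "plantation": 1, "planted": 1,
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class ParseError(ValueError):
    """A cell could not be interpreted; carries the offending row number."""


class EmptyAnalysisError(ValueError):
    """Filtering removed every record, leaving nothing to analyse."""


@dataclass(frozen=True)
class SampleRecord:
    """One measured individual."""

    stand_id: str
    species: str
    origin: int
    activity: float | None
    censored: bool

    def __post_init__(self):
        if self.origin not in (0, 1):
            raise ValueError(f"origin must be 0 (sprout) or 1 (plantation), got {self.origin!r}")
        if not self.censored and not (self.activity is not None and self.activity > 0):
            raise ValueError("non-censored records require a strictly positive activity")


@dataclass
class SampleTable:
    """An ordered collection of sample records with a provenance note.

    Internally a pandas DataFrame with canonical columns
    ``stand, species, origin, activity, censored``; row order is preserved
    by every operation in this module.
    """

    _df: pd.DataFrame
    provenance: str = ""

    @classmethod
    def from_records(cls, records: Iterable[SampleRecord], provenance: str = "") -> "SampleTable":
        rows = [
            (r.stand_id, r.species, r.origin, np.nan if r.activity is None else r.activity, r.censored)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=["stand", "species", "origin", "activity", "censored"])
        return cls(df, provenance)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "SampleTable":
        missing = [c for c in ("stand", "species", "origin", "activity", "censored") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out = df.loc[:, ["stand", "species", "origin", "activity", "censored"]].reset_index(drop=True).copy()
        out["stand"] = out["stand"].astype(str)
        out["species"] = out["species"].astype(str)
        if (out["stand"].str.len() == 0).any() or (out["species"].str.len() == 0).any():
            raise ValueError("stand and species labels must be non-empty strings")
        out["origin"] = out["origin"].astype(int)
        out["activity"] = out["activity"].astype(float)
        out["censored"] = out["censored"].astype(bool)
        return cls(out, provenance)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def records(self) -> list[SampleRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            act = None if pd.isna(row.activity) else float(row.activity)
            out.append(SampleRecord(row.stand, row.species, int(row.origin), act, bool(row.censored)))
        return out

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    @property
    def stand_ids(self) -> list[str]:
        return list(dict.fromkeys(self._df["stand"]))

    @property
    def species_names(self) -> list[str]:
        return list(dict.fromkeys(self._df["species"]))

    def groupby_stand(self):
        """Group in stable first-appearance order of stands."""
        for sid in self.stand_ids:
            yield sid, SampleTable(self._df[self._df["stand"] == sid].reset_index(drop=True), self.provenance)

    def groupby_species(self):
        for sp in self.species_names:
            yield sp, SampleTable(self._df[self._df["species"] == sp].reset_index(drop=True), self.provenance)


@dataclass
class StandSummary:
    """Per-stand moments of log activity over non-censored records."""

    stand_id: str
    n: int
    mean_log: float
    sd_log: float | None
    outlier_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _parse_censored(raw) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unrecognized censored flag {raw!r}")


def _parse_origin(raw, row: int) -> int:
    s = str(raw).strip().lower()
    if s in _ORIGIN_ALIASES:
        return _ORIGIN_ALIASES[s]
    try:
        v = int(float(s))
    except ValueError:
        raise ParseError(f"row {row}: cannot interpret origin value {raw!r}") from None
    if v not in (0, 1):
        raise ParseError(f"row {row}: origin must be 0 or 1, got {v}")
    return v


def read_samples(path: str | Path, column_map: Mapping[str, str] | None = None) -> SampleTable:
    """Read a sample table from CSV.

    Parameters
    ----------
    path : CSV file with one row per individual.
    column_map : optional mapping from canonical names
        (``stand, species, origin, activity, censored``) to the file's
        header names.  Unmapped names fall back to the canonical defaults.
        The ``censored`` column is optional in the file; when absent, rows
        are censored iff their activity is missing or non-positive.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("stand", "species", "origin", "activity"):
        if cols[key] not in raw.columns:
            raise SchemaError(f"missing required column {cols[key]!r} (for field {key!r})")
    has_flag = cols["censored"] in raw.columns

    records: list[SampleRecord] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        cells = dict(zip(raw.columns, row))
        stand = cells[cols["stand"]].strip()
        species = cells[cols["species"]].strip()
        origin = _parse_origin(cells[cols["origin"]], i)
        flagged = _parse_censored(cells[cols["censored"]]) if has_flag else False
        act_raw = cells[cols["activity"]].strip()
        activity: float | None
        if act_raw == "" or act_raw.lower() in ("na", "nan", "nd", "<dl"):
            activity = None
        else:
            try:
                activity = float(act_raw)
            except ValueError:
                if flagged:
                    activity = None
                else:
                    raise ParseError(
                        f"row {i}: non-numeric activity {act_raw!r} on a non-censored row"
                    ) from None
        censored = flagged or activity is None or activity <= 0
        if censored and activity is not None and activity <= 0:
            activity = None
        records.append(SampleRecord(stand, species, origin, activity, censored))
    return SampleTable.from_records(records, provenance=str(path))


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a sample table as CSV (canonical columns, empty cell = no value)."""
    df = table.to_frame()
    df["censored"] = df["censored"].astype(int)
    df.to_csv(path, index=False)


def exclude_censored(table: SampleTable) -> tuple[SampleTable, float]:
    """Drop below-detection records; return the kept table and excluded fraction."""
    if len(table) == 0:
        raise EmptyAnalysisError("empty sample table")
    df = table.to_frame()
    keep = df[~df["censored"]].reset_index(drop=True)
    if len(keep) == 0:
        raise EmptyAnalysisError("all records are censored; nothing left to analyse")
    frac = 1.0 - len(keep) / len(df)
    return SampleTable(keep, table.provenance), frac


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (the type-7 convention).  Fewer than 4
    values cannot support a meaningful IQR: all flags are False and a warning
    is issued.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values; IQR outlier rule not applied", stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation by default
    iqr = q3 - q1
    return (x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)


def stand_summaries(table: SampleTable) -> list[StandSummary]:
    """Per-stand mean and sample SD (n-1 denominator) of log_e activity.

    Expects a censoring-filtered table.  Within-stand outliers are flagged
    by the 1.5 x IQR rule on the log values (all False for stands with fewer
    than 4 records).
    """
    df = table.to_frame()
    if bool(df["censored"].any()):
        raise ValueError("apply exclude_censored() before computing stand summaries")
    out: list[StandSummary] = []
    for sid in table.stand_ids:
        logs = np.log(df.loc[df["stand"] == sid, "activity"].to_numpy(dtype=float))
        n = logs.size
        sd = float(np.std(logs, ddof=1)) if n >= 2 else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = flag_outliers(logs)
        out.append(StandSummary(sid, n, float(np.mean(logs)), sd, flags))
    return out


def summaries_frame(summaries: Iterable[StandSummary]) -> pd.DataFrame:
    """Tabulate stand summaries for CSV export."""
    return pd.DataFrame(
        [
            {
                "stand": s.stand_id,
                "n": s.n,
                "mean_log": s.mean_log,
                "sd_log": np.nan if s.sd_log is None else s.sd_log,
                "n_outliers": int(np.sum(s.outlier_flags)),
            }
            for s in summaries
        ]
    )
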