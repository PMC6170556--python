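"""Reading, validating and writing daily pollutant concentration tables.

A *month table* is a pandas DataFrame with a ``date`` column (unique
calendar days) and one numeric column per indicator — PM2.5, PM10, SO2,
NO2, O3 in µg/m³ and CO in mg/m³.  All validation failures carry row/column
context so a malformed CSV is diagnosable from the error message alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grading import INDICATORS

__all__ = [
    "COLUMNS",
    "DailyRecord",
    "MonthTableError",
    "validate_month_table",
    "read_daily_csv",
    "write_daily_csv",
    "load_shenyang_november",
    "load_monthly_cloud_fixture",
]

COLUMNS = ("date",) + INDICATORS


class MonthTableError(ValueError):
    """A daily concentration table failed validation."""


@dataclass(frozen=True)
class DailyRecord:
    """One day's concentrations (µg/m³ except CO in mg/m³)."""

    date: object
    pm25: float
    pm10: float
    so2: float
    co: float
    no2: float
    o3: float

    def as_mapping(self) -> dict[str, float]:
        return {
            "PM2.5": self.pm25,
            "PM10": self.pm10,
            "SO2": self.so2,
            "CO": self.co,
            "NO2": self.no2,
            "O3": self.o3,
        }


def validate_month_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a daily table in place-independent fashion.

    Checks the seven expected columns, parseable dates (unique within the
    table) and finite non-negative concentrations.  Returns a copy with
    parsed dates and float concentration columns.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MonthTableError(f"missing column(s): {', '.join(missing)}")
    out = df.loc[:, list(COLUMNS)].copy()
    try:
        out["date"] = pd.to_datetime(out["date"]).dt.date
    except (ValueError, TypeError) as exc:
        raise MonthTableError(f"unparseable date: {exc}") from exc
    if out["date"].duplicated().any():
        dup = out.loc[out["date"].duplicated(), "date"].iloc[0]
        raise MonthTableError(f"duplicate date {dup}")
    for col in INDICATORS:
        values = pd.to_numeric(out[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = out.loc[bad.idxmax()]
            raise MonthTableError(
                f"non-numeric value {df[col].iloc[bad.idxmax()]!r} in column "
                f"{col!r} on {row['date']}"
            )
        if (values < 0).any():
            row = out.loc[(values < 0).idxmax()]
            raise MonthTableError(
                f"negative concentration {values.min()} in column {col!r} "
                f"on {row['date']}"
            )
        out[col] = values.astype(float)
    return out.reset_index(drop=True)


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily concentration CSV (ISO dates, dot decimals) and
    validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MonthTableError(f"{path.name}: cannot parse CSV: {exc}") from exc
    try:
        return validate_month_table(df)
    except MonthTableError as exc:
        raise MonthTableError(f"{path.name}: {exc}") from exc


def write_daily_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated month table; read → write → read is lossless."""
    validate_month_table(df).to_csv(path, index=False)


def records(df: pd.DataFrame):
    """Iterate a validated month table as DailyRecord objects."""
    for _, row in df.iterrows():
        yield DailyRecord(
            date=row["date"],
            pm25=row["PM2.5"],
            pm10=row["PM10"],
            so2=row["SO2"],
            co=row["CO"],
            no2=row["NO2"],
            o3=row["O3"],
        )


def load_shenyang_november() -> pd.DataFrame:
    """The packaged Shenyang November 2016 daily table (30 days)."""
    with resources.files("aircloud.data").joinpath("shenyang_2016_11.csv").open() as fh:
        return validate_month_table(pd.read_csv(fh))


def load_monthly_cloud_fixture() -> dict:
    """The packaged 12-month cloud-model fixture (published monthly
    characteristics and levels, Shenyang Nov 2016 – Oct 2017)."""
    import json

    with resources.files("aircloud.data").joinpath(
        "shenyang_monthly_clouds.json"
    ).open() as fh:
        return json.load(fh)
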