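"""Regulatory grading tables, standard clouds and IAQI/AQI computation.

The grading table carries, per pollutant, the ordered concentration bands
delimiting the five Chinese daily air-quality levels (Good … Heavily
Polluted, per GB 3095-2012 / HJ 633-2012), plus the index-scale bands with
upper limits 50/100/150/200/300.  Each band maps to a *standard cloud* by
the bilateral-constraint formulas

    Ex = (Cmin + Cmax) / 2,   En = (Cmax − Cmin) / 6,   He = k · En

with k = 0.1 by default.  The individual air quality index (IAQI) is the
exact piecewise-linear interpolation of a concentration against the index
bands; the AQI of a day is the maximum IAQI over all pollutants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping
import warnings

from .cloud import CloudModel

__all__ = [
    "INDICATORS",
    "LevelBand",
    "GradingTable",
    "StandardCloudSet",
    "IaqiResult",
    "AqiResult",
    "GradingTableError",
    "load_grading_table",
    "default_grading_table",
    "standard_cloud_from_band",
    "build_standard_set",
    "iaqi",
    "aqi_record",
]

#: Canonical indicator order used throughout (matches the regulatory table).
INDICATORS = ("PM2.5", "PM10", "SO2", "CO", "NO2", "O3")

#: Reserved name for the index scale inside a StandardCloudSet.
AQI_KEY = "AQI"


class GradingTableError(ValueError):
    """A grading-table document failed schema validation."""


@dataclass(frozen=True)
class LevelBand:
    """One grading level's concentration band [cmin, cmax]."""

    level: int
    label: str
    cmin: float
    cmax: float

    def __post_init__(self) -> None:
        if not self.cmin < self.cmax:
            raise ValueError(
                f"band {self.label!r}: cmin ({self.cmin}) must be < cmax ({self.cmax})"
            )


@dataclass(frozen=True)
class IndicatorScale:
    """Ordered bands of one indicator (band 1 starts at 0)."""

    name: str
    unit: str
    bands: tuple[LevelBand, ...]


@dataclass(frozen=True)
class GradingTable:
    """Per-indicator concentration bands plus the AQI index-scale bands."""

    indicators: Mapping[str, IndicatorScale]
    index_bands: tuple[LevelBand, ...]
    levels: tuple[str, ...]
    name: str = "grading table"

    def scale(self, indicator: str) -> IndicatorScale:
        try:
            return self.indicators[indicator]
        except KeyError:
            raise KeyError(
                f"unknown indicator {indicator!r}; expected one of {list(self.indicators)}"
            ) from None

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(self.indicators)

    def checksum(self) -> str:
        """Stable hex digest of the table contents, for run provenance."""
        import hashlib

        payload = json.dumps(
            {
                name: [b.cmax for b in sc.bands]
                for name, sc in list(self.indicators.items()) + [("__index__", _FakeScale(self.index_bands))]
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class _FakeScale:
    bands: tuple[LevelBand, ...]


def _bands_from_limits(limits: Iterable[float], labels: Iterable[str], where: str) -> tuple[LevelBand, ...]:
    limits = [float(u) for u in limits]
    labels = list(labels)
    if len(limits) != len(labels):
        raise GradingTableError(
            f"{where}: {len(limits)} upper limits but {len(labels)} level labels"
        )
    if any(b <= a for a, b in zip(limits, limits[1:])):
        raise GradingTableError(f"{where}: upper limits must be strictly increasing")
    if limits[0] <= 0:
        raise GradingTableError(f"{where}: first upper limit must be positive")
    lows = [0.0] + limits[:-1]
    return tuple(
        LevelBand(level=i + 1, label=lab, cmin=lo, cmax=hi)
        for i, (lab, lo, hi) in enumerate(zip(labels, lows, limits))
    )


def load_grading_table(source: str | Path | Mapping) -> GradingTable:
    """Build a GradingTable from a JSON document (path or parsed mapping).

    Schema: ``levels`` (ordered labels), ``index_scale.upper_limits``, and
    ``indicators`` mapping each pollutant to ``unit`` + ``upper_limits``.
    Bands are reconstructed as contiguous half-open intervals starting at 0.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    for key in ("levels", "index_scale", "indicators"):
        if key not in doc:
            raise GradingTableError(f"grading table document missing {key!r}")
    labels = tuple(doc["levels"])
    index_bands = _bands_from_limits(doc["index_scale"]["upper_limits"], labels, "index_scale")
    indicators: dict[str, IndicatorScale] = {}
    for name, entry in doc["indicators"].items():
        if "upper_limits" not in entry:
            raise GradingTableError(f"indicator {name!r} missing 'upper_limits'")
        bands = _bands_from_limits(entry["upper_limits"], labels, f"indicator {name!r}")
        indicators[name] = IndicatorScale(name=name, unit=entry.get("unit", ""), bands=bands)
    return GradingTable(
        indicators=indicators,
        index_bands=index_bands,
        levels=labels,
        name=doc.get("name", "grading table"),
    )


def default_grading_table() -> GradingTable:
    """The packaged daily grading table (GB 3095-2012 / HJ 633-2012).

    CO is graded in mg/m³, all other pollutants in µg/m³.
    """
    with resources.files("aircloud.data").joinpath("grading_gb3095.json").open() as fh:
        return load_grading_table(json.load(fh))


def standard_cloud_from_band(band: LevelBand, k: float = 0.1) -> CloudModel:
    """Standard cloud of one grading band via the bilateral-constraint
    formulas: ((cmin+cmax)/2, (cmax−cmin)/6, k·(cmax−cmin)/6)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > 1 / 3:
        warnings.warn(
            f"hyper-entropy ratio k={k} exceeds the customary upper bound of 1/3",
            stacklevel=2,
        )
    en = (band.cmax - band.cmin) / 6.0
    return CloudModel(ex=(band.cmin + band.cmax) / 2.0, en=en, he=k * en)


@dataclass(frozen=True)
class StandardCloudSet:
    """Standard clouds for every (indicator, level) cell plus the AQI row."""

    k: float
    clouds: Mapping[tuple[str, int], CloudModel]
    levels: tuple[str, ...]

    def level_clouds(self, indicator: str) -> tuple[CloudModel, ...]:
        """All levels' standard clouds for one indicator (or "AQI"),
        ordered by increasing severity."""
        out = []
        for level in range(1, len(self.levels) + 1):
            key = (indicator, level)
            if key not in self.clouds:
                raise KeyError(f"no standard cloud for {indicator!r} level {level}")
            out.append(self.clouds[key])
        return tuple(out)

    def expectation_matrix(self, indicators: Iterable[str]) -> list[list[float]]:
        """Level × indicator matrix of standard-cloud expectations (the
        limiting-value matrix consumed by grey relational analysis)."""
        return [
            [self.clouds[(ind, level)].ex for ind in indicators]
            for level in range(1, len(self.levels) + 1)
        ]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "levels": list(self.levels),
            "clouds": {
                f"{ind}/{level}": list(cm.as_tuple())
                for (ind, level), cm in self.clouds.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def build_standard_set(table: GradingTable, k: float = 0.1) -> StandardCloudSet:
    """Standard clouds for the whole table: each indicator's five bands and
    the index-scale bands (keyed "AQI")."""
    clouds: dict[tuple[str, int], CloudModel] = {}
    for band in table.index_bands:
        clouds[(AQI_KEY, band.level)] = standard_cloud_from_band(band, k)
    for name, sc in table.indicators.items():
        for band in sc.bands:
            clouds[(name, band.level)] = standard_cloud_from_band(band, k)
    return StandardCloudSet(k=k, clouds=clouds, levels=table.levels)


@dataclass(frozen=True)
class IaqiResult:
    """One pollutant's individual index with the breakpoint segment used."""

    indicator: str
    value: float
    segment: tuple[float, float, float, float]  # (BP_Lo, BP_Hi, IAQI_Lo, IAQI_Hi)
    above_scale: bool = False


def iaqi(
    indicator: str,
    concentration: float,
    table: GradingTable,
    rounding: bool = False,
) -> IaqiResult:
    """Individual air quality index by exact linear interpolation.

    The band with BP_Lo < C ≤ BP_Hi is located (band 1 includes 0) and the
    concentration mapped linearly onto the matching index band.
    Concentrations above the top breakpoint extrapolate on the last segment
    with ``above_scale`` set.  ``rounding`` applies the regulation's integer
    ceiling; off by default, because exact interpolation is what reproduces
    published index clouds.
    """
    if not concentration >= 0:
        raise ValueError(
            f"{indicator}: concentration must be >= 0 and finite, got {concentration}"
        )
    scale = table.scale(indicator)
    bands = scale.bands
    idx = None
    for i, band in enumerate(bands):
        if concentration <= band.cmax:
            idx = i
            break
    above = idx is None
    if above:
        idx = len(bands) - 1  # extrapolate on the top segment
    band = bands[idx]
    ib = table.index_bands[idx]
    slope = (ib.cmax - ib.cmin) / (band.cmax - band.cmin)
    value = slope * (concentration - band.cmin) + ib.cmin
    if rounding:
        import math

        value = float(math.ceil(value))
    return IaqiResult(
        indicator=indicator,
        value=value,
        segment=(band.cmin, band.cmax, ib.cmin, ib.cmax),
        above_scale=above,
    )


@dataclass(frozen=True)
class AqiResult:
    """Daily AQI: the maximum IAQI, its dominant indicator(s) and the full
    per-indicator breakdown."""

    aqi: float
    dominant: tuple[str, ...]
    iaqis: Mapping[str, IaqiResult]


def aqi_record(
    record: Mapping[str, float],
    table: GradingTable,
    rounding: bool = False,
) -> AqiResult:
    """AQI of one day's record: max over each indicator's IAQI.

    ``record`` maps every indicator in the table to its daily concentration;
    a missing or non-numeric value is a named validation error.  Ties on the
    maximum report all dominant indicators.
    """
    results: dict[str, IaqiResult] = {}
    for name in table.indicator_names:
        if name not in record or record[name] is None:
            raise ValueError(f"record is missing indicator {name!r}")
        results[name] = iaqi(name, float(record[name]), table, rounding=rounding)
    aqi_value = max(r.value for r in results.values())
    dominant = tuple(n for n, r in results.items() if r.value == aqi_value)
    return AqiResult(aqi=aqi_value, dominant=dominant, iaqis=results)
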