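"""Synthetic daily pollutant series with seasonal structure.

Stands in for multi-month monitoring archives that cannot be
redistributed.  Each indicator's daily concentration is log-normal around a
seasonally modulated baseline:

    x(day in month m) = baseline · exp(A · cos(2π(m − peak)/12)) · exp(σ·Z)

with Z a standard normal draw.  The default parameters emulate a northern
Chinese industrial city: PM2.5, SO2 and NO2 peak in winter (coal-fired
heating), O3 peaks in summer (photochemistry), PM10 and CO are roughly flat
year-round.  Baselines are set so that annual magnitudes resemble the
Shenyang 2016–17 monthly expectations.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grading import INDICATORS

__all__ = ["IndicatorSpec", "SyntheticSpec", "generate_synthetic_month", "generate_synthetic_year"]

_JANUARY, _JULY = 1, 7


@dataclass(frozen=True)
class IndicatorSpec:
    """Generator parameters for one indicator.

    baseline is the seasonal-median concentration (indicator unit);
    log_spread the log-scale standard deviation σ of daily values;
    amplitude the seasonal log-amplitude A (0 = flat); peak_month the month
    (1–12) where the seasonal multiplier is largest.
    """

    baseline: float
    log_spread: float = 0.35
    amplitude: float = 0.0
    peak_month: int = _JANUARY

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if self.log_spread < 0 or self.amplitude < 0:
            raise ValueError("log_spread and amplitude must be >= 0")
        if not 1 <= self.peak_month <= 12:
            raise ValueError(f"peak_month must be in 1..12, got {self.peak_month}")

    def seasonal_baseline(self, month: int) -> float:
        return self.baseline * float(
            np.exp(self.amplitude * np.cos(2 * np.pi * (month - self.peak_month) / 12))
        )


def _default_indicators() -> dict[str, IndicatorSpec]:
    return {
        "PM2.5": IndicatorSpec(baseline=45.0, log_spread=0.45, amplitude=0.5, peak_month=_JANUARY),
        "PM10": IndicatorSpec(baseline=95.0, log_spread=0.40, amplitude=0.0),
        "SO2": IndicatorSpec(baseline=35.0, log_spread=0.45, amplitude=0.9, peak_month=_JANUARY),
        "CO": IndicatorSpec(baseline=0.95, log_spread=0.35, amplitude=0.0),
        "NO2": IndicatorSpec(baseline=40.0, log_spread=0.30, amplitude=0.3, peak_month=_JANUARY),
        "O3": IndicatorSpec(baseline=85.0, log_spread=0.35, amplitude=0.45, peak_month=_JULY),
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generator configuration: per-indicator parameters plus seed."""

    indicators: Mapping[str, IndicatorSpec] = field(default_factory=_default_indicators)
    seed: int = 20161101

    def __post_init__(self) -> None:
        missing = [n for n in INDICATORS if n not in self.indicators]
        if missing:
            raise ValueError(f"spec missing indicator(s): {', '.join(missing)}")


def generate_synthetic_month(
    spec: SyntheticSpec, year: int, month: int, days: int | None = None
) -> pd.DataFrame:
    """One calendar month of synthetic daily concentrations.

    Deterministic given (spec.seed, year, month): the month's substream is
    seeded independently so generating months in any order is reproducible.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    n_days = days if days is not None else calendar.monthrange(year, month)[1]
    if n_days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng([spec.seed, year, month])
    data: dict[str, object] = {
        "date": [pd.Timestamp(year, month, d + 1).date() for d in range(n_days)]
    }
    for name in INDICATORS:
        ind = spec.indicators[name]
        centre = ind.seasonal_baseline(month)
        data[name] = centre * np.exp(ind.log_spread * rng.standard_normal(n_days))
    return pd.DataFrame(data)


def generate_synthetic_year(
    spec: SyntheticSpec, start_year: int = 2016, start_month: int = 11
) -> list[tuple[str, pd.DataFrame]]:
    """Twelve consecutive synthetic months, labelled "YYYY-MM"."""
    out = []
    year, month = start_year, start_month
    for _ in range(12):
        out.append((f"{year}-{month:02d}", generate_synthetic_month(spec, year, month)))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return out
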