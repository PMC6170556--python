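"""End-to-end monthly and multi-month air-quality assessment.

For one month of daily data the pipeline

1. estimates each pollutant's cloud model (Ex, En, He) from its daily
   concentrations with the backward generator,
2. classifies each cloud against the pollutant's standard clouds by maximum
   similarity (quantitative level) and also reports the pair of levels whose
   standard expectations bracket the assessed expectation (the qualitative
   reading "between level a and level b"),
3. computes the daily AQI series (max of per-pollutant sub-indices), its
   cloud and its level on the index scale,
4. cross-checks the pollutant levels with grey relational analysis on the
   same expectations and reports the concordance.

Everything here is deterministic: no sampling enters estimation,
classification, AQI or the grey cross-check (forward generation is used only
for rendering cloud pictures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cloud import CloudModel, SimilarityVector, backward_estimate, classify
from .gra import GreyAssessment, GreyInputs, grey_assess
from .grading import AQI_KEY, GradingTable, StandardCloudSet, aqi_record
from .io import validate_month_table

__all__ = [
    "IndicatorAssessment",
    "AqiAssessment",
    "ConcordanceReport",
    "MonthlyAssessment",
    "SeasonalTrajectory",
    "assess_month",
    "assess_series",
    "concordance",
    "qualitative_bracket",
]

WINTER_MONTHS = (12, 1, 2)
SUMMER_MONTHS = (6, 7, 8)


@dataclass(frozen=True)
class IndicatorAssessment:
    """One pollutant's monthly result: estimated cloud, full similarity
    vector, quantitative level and the qualitative level bracket."""

    indicator: str
    cloud: CloudModel
    similarity: SimilarityVector
    level: int
    bracket: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "cloud": list(self.cloud.as_tuple()),
            "lambdas": list(self.similarity.lambdas),
            "level": self.level,
            "qualitative_bracket": list(self.bracket),
        }


@dataclass(frozen=True)
class AqiAssessment:
    """The month's AQI stage: daily index values, their cloud and level."""

    daily: tuple[float, ...]
    dominant: tuple[tuple[str, ...], ...]
    cloud: CloudModel
    similarity: SimilarityVector
    level: int
    bracket: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "daily_aqi": list(self.daily),
            "dominant": [list(d) for d in self.dominant],
            "cloud": list(self.cloud.as_tuple()),
            "lambdas": list(self.similarity.lambdas),
            "level": self.level,
            "qualitative_bracket": list(self.bracket),
        }


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between cloud-model and grey-relational levels."""

    indicators: tuple[str, ...]
    cloud_levels: tuple[int, ...]
    gra_levels: tuple[int, ...]
    agree: tuple[bool, ...]

    @property
    def agree_count(self) -> int:
        return sum(self.agree)

    @property
    def total(self) -> int:
        return len(self.agree)

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "cloud_levels": list(self.cloud_levels),
            "gra_levels": list(self.gra_levels),
            "agree": list(self.agree),
            "agree_count": self.agree_count,
            "total": self.total,
        }


@dataclass(frozen=True)
class MonthlyAssessment:
    """Complete one-month report."""

    month: str
    indicators: Mapping[str, IndicatorAssessment]
    aqi: AqiAssessment | None
    gra: GreyAssessment | None
    concordance: ConcordanceReport | None

    @property
    def levels(self) -> dict[str, int]:
        return {name: a.level for name, a in self.indicators.items()}

    def to_dict(self) -> dict:
        return {
            "month": self.month,
            "indicators": {n: a.to_dict() for n, a in self.indicators.items()},
            "aqi": self.aqi.to_dict() if self.aqi else None,
            "gra": {
                "d": list(self.gra.d),
                "xi": self.gra.xi.tolist(),
                "r": list(self.gra.r),
                "levels": list(self.gra.levels),
            }
            if self.gra
            else None,
            "concordance": self.concordance.to_dict() if self.concordance else None,
        }


def qualitative_bracket(ex: float, standards: Sequence[CloudModel]) -> tuple[int, ...]:
    """Levels whose standard expectations bracket ``ex``.

    An expectation between two adjacent standard-cloud centres reads
    qualitatively as "between level j and level j+1"; outside the range of
    centres it collapses to the single extreme level.
    """
    centres = [s.ex for s in standards]
    if ex <= centres[0]:
        return (1,)
    if ex >= centres[-1]:
        return (len(centres),)
    for j in range(len(centres) - 1):
        if centres[j] <= ex <= centres[j + 1]:
            return (j + 1, j + 2)
    raise AssertionError("unreachable: standard centres must be increasing")


def _classify_cloud(
    cloud: CloudModel, standards: Sequence[CloudModel]
) -> tuple[SimilarityVector, int, tuple[int, ...]]:
    sim = classify(cloud, standards)
    return sim, sim.best_level, qualitative_bracket(cloud.ex, standards)


def assess_month(
    records: pd.DataFrame,
    standards: StandardCloudSet,
    table: GradingTable,
    rho: float = 0.5,
    month: str | None = None,
) -> MonthlyAssessment:
    """Assess one month of daily data end to end.

    ``records`` is a daily table (validated here); at least two rows are
    required for the backward generator.  Indicator clouds, the AQI cloud,
    grey relational levels and their concordance with the cloud levels are
    all derived from the same rows.
    """
    df = validate_month_table(records)
    if len(df) < 2:
        raise ValueError(f"need at least 2 daily records, got {len(df)}")
    if month is None:
        first = df["date"].iloc[0]
        month = f"{first.year}-{first.month:02d}"

    names = table.indicator_names
    indicator_results: dict[str, IndicatorAssessment] = {}
    for name in names:
        cloud = backward_estimate(df[name].to_numpy())
        sim, level, bracket = _classify_cloud(cloud, standards.level_clouds(name))
        indicator_results[name] = IndicatorAssessment(
            indicator=name, cloud=cloud, similarity=sim, level=level, bracket=bracket
        )

    # daily AQI series -> index-scale cloud
    daily_aqi, dominant = [], []
    for _, row in df.iterrows():
        res = aqi_record({n: row[n] for n in names}, table)
        daily_aqi.append(res.aqi)
        dominant.append(res.dominant)
    aqi_cloud = backward_estimate(np.asarray(daily_aqi))
    aqi_sim, aqi_level, aqi_bracket = _classify_cloud(
        aqi_cloud, standards.level_clouds(AQI_KEY)
    )
    aqi_result = AqiAssessment(
        daily=tuple(daily_aqi),
        dominant=tuple(dominant),
        cloud=aqi_cloud,
        similarity=aqi_sim,
        level=aqi_level,
        bracket=aqi_bracket,
    )

    # grey relational cross-check on the same expectations
    a = np.array([indicator_results[n].cloud.ex for n in names])
    b = np.array(standards.expectation_matrix(names))
    gra = grey_assess(GreyInputs(a=a, b=b, rho=rho, indicators=tuple(names)))
    report = concordance(
        {n: indicator_results[n].level for n in names},
        dict(zip(names, gra.levels)),
    )

    return MonthlyAssessment(
        month=month,
        indicators=indicator_results,
        aqi=aqi_result,
        gra=gra,
        concordance=report,
    )


def concordance(
    cloud_levels: Mapping[str, int] | Sequence[int],
    gra_levels: Mapping[str, int] | Sequence[int],
) -> ConcordanceReport:
    """Per-indicator agreement between two level assignments."""
    if isinstance(cloud_levels, Mapping) and isinstance(gra_levels, Mapping):
        if set(cloud_levels) != set(gra_levels):
            raise ValueError("level mappings cover different indicators")
        names = tuple(cloud_levels)
        c = tuple(cloud_levels[n] for n in names)
        g = tuple(gra_levels[n] for n in names)
    else:
        c = tuple(cloud_levels)  # type: ignore[arg-type]
        g = tuple(gra_levels)  # type: ignore[arg-type]
        if len(c) != len(g):
            raise ValueError(f"length mismatch: {len(c)} vs {len(g)} levels")
        names = tuple(str(i) for i in range(len(c)))
    return ConcordanceReport(
        indicators=names,
        cloud_levels=c,
        gra_levels=g,
        agree=tuple(a == b for a, b in zip(c, g)),
    )


@dataclass(frozen=True)
class SeasonalTrajectory:
    """Level trajectories over months plus a winter/summer comparison.

    ``winter_summer`` maps indicator → (mean December–February level, mean
    June–August level); empty when the input months cover neither season.
    """

    months: tuple[str, ...]
    levels: Mapping[str, tuple[int, ...]]
    assessments: tuple[MonthlyAssessment | None, ...]
    winter_summer: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def level_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.levels), index=list(self.months))


def _month_number(month_id: str) -> int:
    try:
        return int(str(month_id).split("-")[1])
    except (IndexError, ValueError):
        raise ValueError(f"month identifier {month_id!r} is not 'YYYY-MM'") from None


def assess_series(
    months: Sequence[tuple[str, pd.DataFrame | Mapping[str, CloudModel]]],
    standards: StandardCloudSet,
    table: GradingTable | None = None,
    rho: float = 0.5,
) -> SeasonalTrajectory:
    """Assess an ordered sequence of months.

    Each month is either a raw daily table (full pipeline, requires
    ``table``) or a mapping indicator → CloudModel of already-estimated
    monthly characteristics, for which only classification runs — AQI and
    grey stages need raw data and are marked unavailable rather than
    imputed.
    """
    if len(months) == 0:
        raise ValueError("need at least one month")
    month_ids: list[str] = []
    per_month_levels: list[dict[str, int]] = []
    assessments: list[MonthlyAssessment | None] = []
    names: tuple[str, ...] | None = None

    for month_id, payload in months:
        month_ids.append(str(month_id))
        if isinstance(payload, pd.DataFrame):
            if table is None:
                raise ValueError("raw monthly data requires a grading table")
            ma = assess_month(payload, standards, table, rho=rho, month=str(month_id))
            per_month_levels.append(ma.levels)
            assessments.append(ma)
            month_names = tuple(ma.levels)
        else:
            levels: dict[str, int] = {}
            for name, cloud in payload.items():
                sim = classify(cloud, standards.level_clouds(name))
                levels[name] = sim.best_level
            per_month_levels.append(levels)
            assessments.append(None)
            month_names = tuple(levels)
        if names is None:
            names = month_names
        elif set(names) != set(month_names):
            raise ValueError("months cover different indicator sets")

    assert names is not None
    levels_by_ind = {
        n: tuple(m[n] for m in per_month_levels) for n in names
    }

    winter_summer: dict[str, tuple[float, float]] = {}
    numbers = [_month_number(m) for m in month_ids]
    win = [i for i, m in enumerate(numbers) if m in WINTER_MONTHS]
    sumr = [i for i, m in enumerate(numbers) if m in SUMMER_MONTHS]
    if win and sumr:
        for n in names:
            seq = levels_by_ind[n]
            winter_summer[n] = (
                float(np.mean([seq[i] for i in win])),
                float(np.mean([seq[i] for i in sumr])),
            )

    return SeasonalTrajectory(
        months=tuple(month_ids),
        levels=levels_by_ind,
        assessments=tuple(assessments),
        winter_summer=winter_summer,
    )
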