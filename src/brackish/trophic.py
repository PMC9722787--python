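"""Percentile-based indicator statistics and trophic-state classification.

Each indicator is summarised by a configurable percentile of the seasonal
values (linear interpolation between order statistics) and classified by
fixed concentration bounds. Dissolved silica is orientation-reversed:
higher concentrations are better (less depleted).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import WaterSample, ValidationError, derive_nutrients, _is_missing

GOOD = "good_oligotrophic"
FAIR = "fair_mesotrophic"
POOR = "poor_eutrophic"
VERY_POOR = "very_poor_hypereutrophic"
STATES = (GOOD, FAIR, POOR, VERY_POOR)

INDICATORS = ("din", "dip", "dsi", "chla")


@dataclass
class TrophicThreshold:
    """Percentile choice and class bounds for one indicator."""

    indicator: str
    percentile: float
    bounds: tuple[float, ...]
    reversed: bool = False

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValidationError(f"unknown indicator {self.indicator!r}")
        if not 0.0 < self.percentile < 100.0:
            raise ValidationError("percentile must be in (0, 100)")
        if list(self.bounds) != sorted(self.bounds) or len(set(self.bounds)) != len(self.bounds):
            raise ValidationError(f"bounds must be strictly ordered: {self.bounds!r}")


def default_thresholds() -> dict[str, TrophicThreshold]:
    return {
        "din": TrophicThreshold("din", 80.0, (0.1, 1.0)),
        "dip": TrophicThreshold("dip", 80.0, (0.01, 0.1)),
        "dsi": TrophicThreshold("dsi", 10.0, (2.0, 5.0), reversed=True),
        "chla": TrophicThreshold("chla", 90.0, (5.0, 20.0, 60.0)),
    }


@dataclass
class TrophicReport:
    indicator: str
    season: str
    statistic: float
    state: str
    percentile: float = math.nan


def indicator_statistic(values: Iterable[float],
                        threshold: TrophicThreshold) -> float:
    """The configured percentile (linear interpolation) of the values."""
    data = [v for v in values if not _is_missing(v)]
    if not data:
        raise ValidationError(
            f"no non-missing values for indicator {threshold.indicator!r}")
    return float(np.percentile(data, threshold.percentile, method="linear"))


def classify(indicator: str, statistic: float,
             thresholds: Mapping[str, TrophicThreshold] | None = None) -> str:
    """Map an indicator statistic to its trophic state.

    Boundary closures follow the classification scheme as written: DIN/DIP
    fair is left-closed ([0.1, 1) etc., exact 1.0 closing upward to poor);
    chlorophyll-a classes are right-closed (5 is still good); reversed DSi
    classes are left-open (exactly 5 is fair, exactly 2 is poor).
    """
    if not math.isfinite(statistic):
        raise ValidationError(f"statistic must be finite, got {statistic!r}")
    thresholds = thresholds or default_thresholds()
    if indicator not in thresholds:
        raise ValidationError(f"unknown indicator {indicator!r}")
    t = thresholds[indicator]
    if t.reversed:
        # e.g. DSi: good > 5, fair (2, 5], poor <= 2
        hi = t.bounds[-1]
        if statistic > hi:
            return GOOD
        if statistic > t.bounds[0]:
            return FAIR
        return POOR
    if indicator in ("din", "dip"):
        if statistic < t.bounds[0]:
            return GOOD
        if statistic < t.bounds[1]:
            return FAIR
        return POOR
    # chla: good <= 5 < fair <= 20 < poor <= 60 < very poor
    b = t.bounds
    if statistic <= b[0]:
        return GOOD
    if statistic <= b[1]:
        return FAIR
    if len(b) > 2 and statistic > b[2]:
        return VERY_POOR
    return POOR


def chla_estuary_class(p_chla: float) -> str:
    """Three-state estuary class from a chlorophyll-a percentile value."""
    if p_chla < 0:
        raise ValidationError("chlorophyll-a must be >= 0")
    if p_chla <= 5.0:
        return "oligotrophic"
    if p_chla <= 20.0:
        return "mesotrophic"
    return "eutrophic"


def trophic_report(samples: Sequence[WaterSample], season: str,
                   thresholds: Mapping[str, TrophicThreshold] | None = None
                   ) -> list[TrophicReport]:
    """Per-indicator percentile statistic and state for one season."""
    thresholds = thresholds or default_thresholds()
    pool = [s for s in samples if s.season == season]
    if not pool:
        raise ValidationError(f"no samples for season {season!r}")

    def _values(indicator: str) -> list[float]:
        if indicator == "din":
            out = []
            for s in pool:
                try:
                    out.append(derive_nutrients(s).din)
                except ValidationError:
                    out.append(math.nan)
            return out
        attr = {"dip": "po4_p", "dsi": "dsi", "chla": "chla"}[indicator]
        return [getattr(s, attr) for s in pool]

    reports = []
    for indicator in INDICATORS:
        t = thresholds[indicator]
        statistic = indicator_statistic(_values(indicator), t)
        reports.append(TrophicReport(
            indicator=indicator, season=season, statistic=statistic,
            state=classify(indicator, statistic, thresholds),
            percentile=t.percentile))
    return reports
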