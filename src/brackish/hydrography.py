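"""Mixing classification, Venice salinity zoning, isohaline location and
habitat-suitability screening from CTD casts."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core_io import CTDCast, ValidationError

WELL_MIXED = "well_mixed"
PARTIALLY_MIXED = "partially_mixed"
STRATIFIED = "stratified"
UNDEFINED = "undefined"

VENICE_CLASSES = ("freshwater", "oligohaline", "mesohaline", "polyhaline", "euhaline")

#: Half-open [low, high) Venice class boundaries in PSU.
DEFAULT_VENICE_BOUNDARIES = (0.5, 5.0, 18.0, 30.0)
DEFAULT_MIXING_THRESHOLDS = (0.1, 1.0)

# Nested habitat salinity windows (PSU); spawning is the most restrictive.
SPAWNING_MAX = 0.1   # exclusive
NURSERY_MAX = 1.0    # inclusive
BROOD_MAX = 2.0      # inclusive


@dataclass
class StratificationResult:
    """Surface/bottom salinity contrast of one cast and its mixing class.

    ``n_s`` is the surface-to-bottom salinity difference normalised by the
    depth-mean salinity ``s_m = (s_bot + s_sur) / 2``.
    """

    s_sur: float
    s_bot: float
    delta_s: float
    s_m: float
    n_s: float
    mixing_class: str
    station_id: str = ""
    date: str = ""
    axis_km: float = math.nan


@dataclass
class HabitatAssessment:
    salinity: float
    suitable_stages: frozenset[str]
    venice_class: str


def stratification(cast: CTDCast,
                   thresholds: tuple[float, float] = DEFAULT_MIXING_THRESHOLDS
                   ) -> StratificationResult:
    """Classify a cast as well-mixed / partially mixed / stratified.

    Surface and bottom are the first and last recorded levels. A wholly
    fresh column (``s_m = 0``) has no defined mixing class.
    """
    if len(cast.depths) < 2:
        raise ValidationError("stratification needs >= 2 depth levels")
    low, high = thresholds
    s_sur, s_bot = cast.s_sur, cast.s_bot
    delta = s_bot - s_sur
    s_m = 0.5 * (s_bot + s_sur)
    if s_m == 0:
        n_s, mixing = math.nan, UNDEFINED
    else:
        n_s = delta / s_m
        if n_s < low:
            mixing = WELL_MIXED
        elif n_s <= high:
            mixing = PARTIALLY_MIXED
        else:
            mixing = STRATIFIED
    return StratificationResult(
        s_sur=s_sur, s_bot=s_bot, delta_s=delta, s_m=s_m, n_s=n_s,
        mixing_class=mixing, station_id=cast.station_id,
        date=cast.date.isoformat(), axis_km=cast.axis_km)


def venice_class(salinity: float,
                 boundaries: Sequence[float] = DEFAULT_VENICE_BOUNDARIES) -> str:
    """Venice salinity zone; boundaries are half-open on the low side."""
    if salinity < 0:
        raise ValidationError(f"salinity must be >= 0, got {salinity!r}")
    for name, bound in zip(VENICE_CLASSES, boundaries):
        if salinity < bound:
            return name
    return VENICE_CLASSES[len(boundaries)]


def habitat_suitability(salinity: float) -> HabitatAssessment:
    """Which hilsa life stages the salinity suits (nested windows)."""
    if salinity < 0:
        raise ValidationError(f"salinity must be >= 0, got {salinity!r}")
    stages = set()
    if salinity < SPAWNING_MAX:
        stages.add("spawning")
    if salinity <= NURSERY_MAX:
        stages.add("nursery")
    if salinity <= BROOD_MAX:
        stages.add("brood")
    return HabitatAssessment(salinity=salinity,
                             suitable_stages=frozenset(stages),
                             venice_class=venice_class(salinity))


def isohaline_position(section: Sequence[CTDCast], iso: float = 2.0) -> float | None:
    """Along-axis position of the near-bottom isohaline.

    Linear interpolation of bottom salinity against axis_km at the first
    landward crossing (scanning from the estuary head seaward); an exact hit
    returns that cast's position. Returns None when the whole section sits on
    one side of ``iso``.
    """
    axis = [c.axis_km for c in section]
    if any(b <= a for a, b in zip(axis, axis[1:])):
        raise ValidationError("section casts must be sorted by increasing axis_km")
    bottom = [c.s_bot for c in section]
    for i, (x, s) in enumerate(zip(axis, bottom)):
        if s == iso:
            return x
        if i + 1 < len(section):
            s_next = bottom[i + 1]
            if (s - iso) * (s_next - iso) < 0:
                return x + (axis[i + 1] - x) * (iso - s) / (s_next - s)
    return None
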