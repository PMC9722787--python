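"""Seeded generators for water-quality panels, CTD salinity sections and
water/gut taxon count tables with the statistical structure the analysis
stages assume.

Noise model: each panel parameter is drawn from a normal law truncated to
its physical range, centred on the seasonal station location with spread
``se * sqrt(n_eff)``. Count tables are multinomial over phyla (percent
compositions renormalised), split uniformly over the genus inventory.
Identical seed and spec give byte-identical outputs.
"""
from __future__ import annotations

import copy
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _defaults as D
from .core_io import (CTDCast, TaxonCountTable, TaxonRow, ValidationError,
                      WaterSample, PARAMETERS, DRY, WET)

# fish length (cm) -> weight (g) allometry spanning ~109 g at 18 cm to ~810 g at 35 cm
_WEIGHT_A, _WEIGHT_B = 0.01774, 3.018


@dataclass
class ScenarioSpec:
    """Complete description of a synthetic sampling campaign."""

    stations: tuple[tuple[str, float], ...] = D.STATIONS
    sites_per_station: Mapping[str, int] = field(
        default_factory=lambda: dict(D.SITES_PER_STATION))
    dry_months: tuple[int, ...] = D.DRY_MONTHS
    wet_months: tuple[int, ...] = D.WET_MONTHS
    water_panel: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]] = field(
        default_factory=lambda: copy.deepcopy(D.WATER_PANEL))
    water_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(D.WATER_COMPOSITION))
    gut_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(D.GUT_COMPOSITION))
    n_fish: int = D.N_FISH
    fish_length_range: tuple[float, float] = D.FISH_LENGTH_RANGE
    density_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(D.DENSITY_RANGE))
    gut_total_range: tuple[int, int] = D.GUT_TOTAL_RANGE
    n_eff: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        axis = [km for _, km in self.stations]
        if len(self.stations) < 2:
            raise ValidationError("need >= 2 stations")
        if any(b <= a for a, b in zip(axis, axis[1:])):
            raise ValidationError("station axis_km must be strictly increasing")
        for source in (self.water_composition, self.gut_composition):
            for season, comp in source.items():
                if any(p < 0 for p in comp.values()):
                    raise ValidationError(
                        f"negative composition percent in season {season!r}")

    @property
    def axis_length_km(self) -> float:
        return self.stations[-1][1]

    def months_for(self, season: str) -> tuple[int, ...]:
        if season == DRY:
            return self.dry_months
        if season == WET:
            return self.wet_months
        raise ValidationError(f"unknown season {season!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioSpec":
        """Build a spec from a (possibly partial) plain mapping, e.g. YAML."""
        kwargs = {}
        simple = {"n_fish", "n_eff", "rng_seed"}
        for key, value in data.items():
            if key == "stations":
                kwargs["stations"] = tuple((str(s), float(km)) for s, km in value)
            elif key in ("dry_months", "wet_months", "fish_length_range",
                         "gut_total_range"):
                kwargs[key] = tuple(value)
            elif key == "density_range":
                kwargs[key] = {s: tuple(v) for s, v in value.items()}
            elif key == "water_panel":
                kwargs[key] = {
                    param: {season: {st: tuple(ls) for st, ls in by_st.items()}
                            for season, by_st in by_season.items()}
                    for param, by_season in value.items()}
            elif key in ("water_composition", "gut_composition",
                         "sites_per_station"):
                kwargs[key] = {k: (dict(v) if isinstance(v, Mapping) else v)
                               for k, v in value.items()}
            elif key in simple:
                kwargs[key] = float(value) if key == "n_eff" else int(value)
            else:
                raise ValidationError(f"unknown scenario key {key!r}")
        return cls(**kwargs)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal; degenerate at loc when scale = 0."""
    if scale < 0:
        raise ValidationError(f"negative spread {scale!r}")
    if scale == 0:
        return np.full(size, loc)
    out = rng.normal(loc, scale, size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(loc, scale, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _bounds_for(parameter: str, season: str) -> tuple[float, float]:
    if parameter == "ph":
        return 0.0, 14.0
    if parameter == "salinity" and season == WET:
        # wet-season construction: fresh everywhere (below the Venice bound)
        return 0.0, 0.4999
    return 0.0, math.inf


def _date_for_month(month: int) -> _dt.date:
    year = 2020 if month >= 7 else 2021
    return _dt.date(year, month, 15)


def simulate_water_panel(spec: ScenarioSpec,
                         seed: int | None = None) -> list[WaterSample]:
    """One record per station x site x month with seeded seasonal structure."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    spread_factor = math.sqrt(spec.n_eff)
    samples: list[WaterSample] = []
    for station, _km in spec.stations:
        n_sites = int(spec.sites_per_station.get(station, 1))
        for season in (DRY, WET):
            months = spec.months_for(season)
            size = n_sites * len(months)
            draws = {}
            for parameter in PARAMETERS:
                loc, se = spec.water_panel[parameter][season][station]
                low, high = _bounds_for(parameter, season)
                draws[parameter] = _truncated_normal(
                    rng, loc, se * spread_factor, low, high, size)
            k = 0
            for site_index in range(1, n_sites + 1):
                for month in months:
                    samples.append(WaterSample(
                        station_id=station,
                        site_id=f"{station}-{site_index}",
                        date=_date_for_month(month),
                        season=season,
                        **{p: float(draws[p][k]) for p in PARAMETERS}))
                    k += 1
    return samples


def simulate_ctd_section(spec: ScenarioSpec, season: str,
                         seed: int | None = None) -> list[CTDCast]:
    """Depth-resolved salinity casts along the estuary axis.

    Dry season: bottom salinity rises monotonically seaward from 0.15 PSU to
    exactly 13 PSU at the axis end; every cast is built well mixed with
    stratification parameter < 0.01. Wet season: all salinities < 0.15 PSU.
    """
    if season not in (DRY, WET):
        raise ValidationError(f"unknown season {season!r}")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    length = spec.axis_length_km
    date = _dt.date(2021, 1, 15) if season == DRY else _dt.date(2020, 8, 15)
    casts: list[CTDCast] = []
    for station, km in spec.stations:
        depth = 8.0 + km / 20.0
        depths = np.linspace(0.5, depth, 6)
        ratio = float(rng.uniform(0.002, 0.009))   # target n_s, < 0.01
        if season == DRY:
            s_bot = 0.15 + (13.0 - 0.15) * (km / length) ** 1.5
        else:
            s_bot = float(rng.uniform(0.02, 0.12))
        # s_sur chosen so that (s_bot - s_sur) / mean == ratio exactly
        s_sur = s_bot * (2.0 - ratio) / (2.0 + ratio)
        salinity = np.linspace(s_sur, s_bot, len(depths))
        casts.append(CTDCast(station_id=station, date=date, axis_km=km,
                             depths=depths.tolist(),
                             salinity=salinity.tolist()))
    return casts


def _composition_probabilities(comp: Mapping[str, float]) -> tuple[list[str], np.ndarray, float]:
    phyla = [p for p in comp if comp[p] > 0]
    if not phyla:
        raise ValidationError("composition is all-zero")
    raw = np.array([comp[p] for p in phyla], dtype=float)
    factor = raw.sum()
    return phyla, raw / factor, float(factor)


def simulate_counts(spec: ScenarioSpec, source: str, season: str,
                    seed: int | None = None,
                    n_tables: int | None = None) -> list[TaxonCountTable]:
    """Multinomial taxon count tables for one source and season.

    Water: one table per station, total cells drawn uniformly from the
    seasonal density range. Gut: one table per fish (default ``n_fish``),
    total prey drawn from ``gut_total_range`` and fish length uniform over
    the configured range. Phylum counts are split uniformly over the genus
    inventory; genus identity carries no signal.
    """
    if source not in ("water", "gut"):
        raise ValidationError(f"unknown source {source!r}")
    if season not in (DRY, WET):
        raise ValidationError(f"unknown season {season!r}")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    comp_map = spec.water_composition if source == "water" else spec.gut_composition
    if season not in comp_map:
        raise ValidationError(f"no {source} composition for season {season!r}")
    phyla, probs, _factor = _composition_probabilities(comp_map[season])

    if source == "water":
        n = len(spec.stations) if n_tables is None else n_tables
        ids = [f"water-{season}-{spec.stations[i % len(spec.stations)][0]}-{i}"
               for i in range(n)]
        lo, hi = spec.density_range[season]
    else:
        n = spec.n_fish if n_tables is None else n_tables
        ids = [f"gut-{season}-{i:03d}" for i in range(n)]
        lo, hi = spec.gut_total_range

    tables: list[TaxonCountTable] = []
    for sample_id in ids:
        total = int(rng.integers(lo, hi + 1))
        phylum_counts = rng.multinomial(total, probs)
        rows: list[TaxonRow] = []
        for phylum, count in zip(phyla, phylum_counts):
            if count == 0:
                continue
            genera = D.GENUS_LISTS.get((source, season, phylum),
                                       (f"{phylum} indet.",))
            split = rng.multinomial(int(count), np.full(len(genera), 1.0 / len(genera)))
            for genus, c in zip(genera, split):
                if c > 0:
                    rows.append(TaxonRow(genus=genus, phylum=phylum, count=int(c)))
        if source == "gut":
            length = float(rng.uniform(*spec.fish_length_range))
            weight = round(_WEIGHT_A * length ** _WEIGHT_B, 1)
            tables.append(TaxonCountTable(source=source, sample_id=sample_id,
                                          rows=rows, fish_length_cm=round(length, 1),
                                          fish_weight_g=weight))
        else:
            tables.append(TaxonCountTable(source=source, sample_id=sample_id,
                                          rows=rows))
    return tables


def renormalisation_factor(comp: Mapping[str, float]) -> float:
    """Sum of the configured percents (the factor divided out before use)."""
    return _composition_probabilities(comp)[2]
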