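"""Domain types, invariants, and tidy-CSV readers/writers shared by all stages.

All tabular exchange happens through three long-format CSV schemas:

``water.csv``
    station_id, site_id, date, [season,] temperature, salinity, do, ph,
    no3_n, no2_n, nh4, po4_p, dsi, chla
``ctd.csv``
    station_id, date, axis_km, depth_m, salinity[, temperature]
``counts.csv``
    source, sample_id, fish_length_cm, fish_weight_g, genus, phylum, count

Dates are ISO-8601. Units are implicit per schema (degC, PSU, mg/L, ug/L).
Missing numeric values are permitted and propagate as NaN; they are never
imputed.
"""
from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class BrackishError(Exception):
    """Base class for package errors."""


class SchemaError(BrackishError):
    """A table is missing mandatory columns or is otherwise malformed."""


class ValidationError(BrackishError):
    """A record violates a domain invariant."""


DRY = "dry"
WET = "wet"
TRANSITIONAL = "transitional"
SEASONS = (DRY, WET)

PHYLA = (
    "Bacillariophyta",
    "Chlorophyta",
    "Cyanobacteria",
    "Euglenophyta",
    "Xanthophyta",
    "Miozoa",
    "Other",
)

#: Water-panel parameters in canonical order.
PARAMETERS = (
    "temperature", "salinity", "do", "ph",
    "no3_n", "no2_n", "nh4", "po4_p", "dsi", "chla",
)

#: Parameters constrained to be non-negative concentrations/amounts.
_CONCENTRATION_FIELDS = (
    "salinity", "do", "no3_n", "no2_n", "nh4", "po4_p", "dsi", "chla",
)

DEFAULT_MONTH_TO_SEASON: dict[int, str] = {
    12: DRY, 1: DRY, 2: DRY, 3: DRY,
    7: WET, 8: WET, 9: WET, 10: WET,
}


def _float_repr(value) -> str:
    # numpy scalars repr as np.float64(...); coerce for lossless CSV output
    return repr(float(value))


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class AnalysisConfig:
    """Tunable defaults shared by the analysis stages."""

    month_to_season: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_MONTH_TO_SEASON))
    venice_boundaries: tuple[float, ...] = (0.5, 5.0, 18.0, 30.0)
    mixing_thresholds: tuple[float, float] = (0.1, 1.0)
    correlation_star_levels: tuple[float, float, float] = (0.05, 0.01, 0.001)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("venice_boundaries", "mixing_thresholds",
                     "correlation_star_levels"):
            values = getattr(self, name)
            ordered = sorted(values) if name != "correlation_star_levels" \
                else sorted(values, reverse=True)
            if list(values) != list(ordered) or len(set(values)) != len(values):
                raise ValidationError(f"{name} must be strictly ordered: {values!r}")

    def season_for_month(self, month: int) -> str:
        return self.month_to_season.get(int(month), TRANSITIONAL)


@dataclass
class WaterSample:
    """One station-date record of the ten-parameter physico-chemical panel."""

    station_id: str
    site_id: str
    date: _dt.date
    season: str
    temperature: float = math.nan
    salinity: float = math.nan
    do: float = math.nan
    ph: float = math.nan
    no3_n: float = math.nan
    no2_n: float = math.nan
    nh4: float = math.nan
    po4_p: float = math.nan
    dsi: float = math.nan
    chla: float = math.nan

    def __post_init__(self) -> None:
        if self.season not in (DRY, WET, TRANSITIONAL):
            raise ValidationError(f"unknown season {self.season!r}")
        for name in _CONCENTRATION_FIELDS:
            value = getattr(self, name)
            if not _is_missing(value) and value < 0:
                raise ValidationError(
                    f"{name} must be >= 0, got {value!r} "
                    f"({self.station_id}/{self.site_id} {self.date})")
        if not _is_missing(self.ph) and not 0.0 <= self.ph <= 14.0:
            raise ValidationError(f"ph out of [0, 14]: {self.ph!r}")


@dataclass
class DerivedNutrients:
    """DIN (sum of the three inorganic N species) and the ammonium share."""

    din: float
    nh4_fraction_of_din: float
    flag: str | None = None


def derive_nutrients(sample: WaterSample) -> DerivedNutrients:
    """Sum the nitrogen species into DIN and report the ammonium fraction.

    Raises :class:`ValidationError` naming the missing species when any of
    no3_n, no2_n, nh4 is absent. When DIN is zero the fraction is undefined
    (NaN) and flagged.
    """
    for name in ("no3_n", "no2_n", "nh4"):
        if _is_missing(getattr(sample, name)):
            raise ValidationError(f"cannot derive DIN: {name} is missing")
    din = sample.no3_n + sample.no2_n + sample.nh4
    if din > 0:
        return DerivedNutrients(din=din, nh4_fraction_of_din=sample.nh4 / din)
    return DerivedNutrients(din=0.0, nh4_fraction_of_din=math.nan,
                            flag="din_zero_fraction_undefined")


@dataclass
class CTDCast:
    """Depth-ordered salinity (and optional temperature) profile."""

    station_id: str
    date: _dt.date
    axis_km: float
    depths: Sequence[float]
    salinity: Sequence[float]
    temperature: Sequence[float] | None = None

    def __post_init__(self) -> None:
        depths = list(self.depths)
        if len(depths) < 2:
            raise ValidationError(
                f"cast {self.station_id} {self.date}: needs >= 2 depth levels")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValidationError(
                f"cast {self.station_id} {self.date}: depths must be strictly increasing")
        if len(self.salinity) != len(depths):
            raise ValidationError("salinity and depths length mismatch")
        if any(s < 0 for s in self.salinity):
            raise ValidationError("salinity must be >= 0")
        if self.temperature is not None and len(self.temperature) != len(depths):
            raise ValidationError("temperature and depths length mismatch")

    @property
    def s_sur(self) -> float:
        return float(self.salinity[0])

    @property
    def s_bot(self) -> float:
        return float(self.salinity[-1])


@dataclass
class TaxonRow:
    genus: str
    phylum: str
    count: int

    def __post_init__(self) -> None:
        if self.phylum not in PHYLA:
            raise ValidationError(f"unknown phylum {self.phylum!r}")
        if not float(self.count).is_integer() or self.count < 0:
            raise ValidationError(
                f"count must be a non-negative integer, got {self.count!r}")
        self.count = int(self.count)


@dataclass
class TaxonCountTable:
    """Genus/phylum counts from one source: a water tow or one fish gut."""

    source: str
    sample_id: str
    rows: list[TaxonRow]
    fish_length_cm: float | None = None
    fish_weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("water", "gut"):
            raise ValidationError(f"source must be 'water' or 'gut', got {self.source!r}")
        genera = [r.genus for r in self.rows]
        if len(set(genera)) != len(genera):
            raise ValidationError(f"duplicate genus in table {self.sample_id!r}")
        if self.source == "gut":
            if self.fish_length_cm is None or _is_missing(self.fish_length_cm):
                raise ValidationError(
                    f"gut table {self.sample_id!r} requires fish_length_cm")
            if not 10.0 <= self.fish_length_cm <= 50.0:
                raise ValidationError(
                    f"fish_length_cm out of accepted range [10, 50]: "
                    f"{self.fish_length_cm!r}")
        else:
            if self.fish_length_cm is not None or self.fish_weight_g is not None:
                raise ValidationError("water tables carry no fish fields")

    def total(self) -> int:
        return sum(r.count for r in self.rows)

    def phylum_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.phylum] = out.get(r.phylum, 0) + r.count
        return out

    def genus_counts(self) -> dict[str, int]:
        return {r.genus: r.count for r in self.rows}


# ---------------------------------------------------------------------------
# CSV I/O

_WATER_REQUIRED = ("station_id", "site_id", "date") + PARAMETERS
_CTD_REQUIRED = ("station_id", "date", "axis_km", "depth_m", "salinity")
_COUNTS_REQUIRED = ("source", "sample_id", "genus", "phylum", "count")


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {column!r}")
    return frame


def _parse_date(value) -> _dt.date:
    return pd.Timestamp(value).date()


def read_water_table(path: str | Path,
                     config: AnalysisConfig | None = None) -> list[WaterSample]:
    """Read ``water.csv`` into validated :class:`WaterSample` records.

    The ``season`` column is optional; absent (or blank) values are filled
    from the configured month-to-season map, with unmapped months labelled
    transitional.
    """
    config = config or AnalysisConfig()
    frame = _read_csv(path, _WATER_REQUIRED)
    samples: list[WaterSample] = []
    for i, row in frame.iterrows():
        date = _parse_date(row["date"])
        season = row.get("season")
        if season is None or (isinstance(season, float) and math.isnan(season)) \
                or (isinstance(season, str) and not season.strip()):
            season = config.season_for_month(date.month)
        try:
            samples.append(WaterSample(
                station_id=str(row["station_id"]),
                site_id=str(row["site_id"]),
                date=date,
                season=str(season),
                **{p: float(row[p]) for p in PARAMETERS},
            ))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return samples


def write_water_table(samples: Iterable[WaterSample], path: str | Path) -> None:
    records = []
    for s in samples:
        rec = {"station_id": s.station_id, "site_id": s.site_id,
               "date": s.date.isoformat(), "season": s.season}
        rec.update({p: getattr(s, p) for p in PARAMETERS})
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format=_float_repr)


def read_ctd_table(path: str | Path) -> list[CTDCast]:
    """Read ``ctd.csv``, grouping rows into depth-sorted casts."""
    frame = _read_csv(path, _CTD_REQUIRED)
    has_temp = "temperature" in frame.columns
    casts: list[CTDCast] = []
    for (station, date), group in frame.groupby(["station_id", "date"], sort=False):
        group = group.sort_values("depth_m")
        axis = group["axis_km"].unique()
        if len(axis) != 1:
            raise ValidationError(
                f"cast {station} {date}: inconsistent axis_km values {axis!r}")
        casts.append(CTDCast(
            station_id=str(station),
            date=_parse_date(date),
            axis_km=float(axis[0]),
            depths=group["depth_m"].astype(float).tolist(),
            salinity=group["salinity"].astype(float).tolist(),
            temperature=(group["temperature"].astype(float).tolist()
                         if has_temp else None),
        ))
    return casts


def write_ctd_table(casts: Iterable[CTDCast], path: str | Path) -> None:
    records = []
    for cast in casts:
        for i, depth in enumerate(cast.depths):
            rec = {"station_id": cast.station_id, "date": cast.date.isoformat(),
                   "axis_km": cast.axis_km, "depth_m": depth,
                   "salinity": cast.salinity[i]}
            if cast.temperature is not None:
                rec["temperature"] = cast.temperature[i]
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format=_float_repr)


def read_counts_table(path: str | Path) -> list[TaxonCountTable]:
    """Read ``counts.csv``, grouping rows into per-sample count tables."""
    frame = _read_csv(path, _COUNTS_REQUIRED)
    tables: list[TaxonCountTable] = []
    for sample_id, group in frame.groupby("sample_id", sort=False):
        sources = group["source"].unique()
        if len(sources) != 1:
            raise ValidationError(
                f"sample {sample_id!r}: mixed sources {sources!r}")
        source = str(sources[0])
        length = weight = None
        if source == "gut":
            if "fish_length_cm" not in frame.columns:
                raise SchemaError("counts.csv: missing mandatory column "
                                  "'fish_length_cm' for gut samples")
            length = float(group["fish_length_cm"].iloc[0])
            if "fish_weight_g" in frame.columns:
                w = group["fish_weight_g"].iloc[0]
                weight = None if _is_missing(float(w)) else float(w)
        rows = []
        for i, row in group.iterrows():
            try:
                rows.append(TaxonRow(genus=str(row["genus"]),
                                     phylum=str(row["phylum"]),
                                     count=float(row["count"])))
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
        tables.append(TaxonCountTable(source=source, sample_id=str(sample_id),
                                      rows=rows, fish_length_cm=length,
                                      fish_weight_g=weight))
    return tables


def write_counts_table(tables: Iterable[TaxonCountTable], path: str | Path) -> None:
    records = []
    for t in tables:
        for r in t.rows:
            records.append({
                "source": t.source, "sample_id": t.sample_id,
                "fish_length_cm": t.fish_length_cm if t.fish_length_cm is not None else "",
                "fish_weight_g": t.fish_weight_g if t.fish_weight_g is not None else "",
                "genus": r.genus, "phylum": r.phylum, "count": r.count,
            })
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format=_float_repr)


def samples_to_frame(samples: Iterable[WaterSample],
                     include_din: bool = True) -> pd.DataFrame:
    """Flatten samples to a DataFrame; optionally append derived DIN."""
    records = []
    for s in samples:
        rec = {"station_id": s.station_id, "site_id": s.site_id,
               "date": s.date, "season": s.season}
        rec.update({p: getattr(s, p) for p in PARAMETERS})
        if include_din:
            missing = any(_is_missing(getattr(s, n)) for n in ("no3_n", "no2_n", "nh4"))
            rec["din"] = math.nan if missing else derive_nutrients(s).din
        records.append(rec)
    return pd.DataFrame.from_records(records)
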