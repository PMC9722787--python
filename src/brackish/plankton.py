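"""Chlorophyll-a from extract absorbances, cell densities from chamber
counts, community composition, and Simpson diversity.

Chlorophyll-a uses the trichromatic equation with a 750-nm turbidity blank:

    chla [ug/L] = (11.64*(A663-A750) - 2.16*(A645-A750) + 0.10*(A630-A750))
                  * v_extract_mL / (V_filtered_L * path_cm)

Cell densities follow the standard gridded-chamber field-count formula with
all chamber geometry configurable.
"""
from __future__ import annotations

import math
import statistics
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import TaxonCountTable, ValidationError

TRICHROMATIC_COEFFICIENTS = (11.64, -2.16, 0.10)


@dataclass
class PigmentExtract:
    """Spectrophotometric absorbances of a pigment extract."""

    a663: float
    a645: float
    a630: float
    a750: float
    extract_volume_ml: float
    filtered_volume_l: float
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.extract_volume_ml <= 0 or self.filtered_volume_l <= 0:
            raise ValidationError("extract and filtered volumes must be > 0")
        if self.path_length_cm <= 0:
            raise ValidationError("path length must be > 0")
        for name in ("a663", "a645", "a630", "a750"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class ChamberCount:
    """A gridded counting-chamber tally of cells over counted fields."""

    cells_counted: int
    fields_counted: int
    field_volume_ml: float
    concentration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.fields_counted < 1:
            raise ValidationError("fields_counted must be >= 1")
        if self.cells_counted < 0:
            raise ValidationError("cells_counted must be >= 0")
        if self.field_volume_ml <= 0 or self.concentration_factor <= 0:
            raise ValidationError("volumes and concentration factor must be > 0")


@dataclass
class DiversityResult:
    """Simpson dominance index D (1 = monoculture) and its reciprocal."""

    d: float
    reciprocal: float | None
    n_taxa: int
    n_total: int


def chlorophyll_a(extract: PigmentExtract) -> float:
    """Chlorophyll-a concentration (ug/L) from a pigment extract.

    Negative trichromatic results are floored at zero with a warning.
    """
    c663, c645, c630 = TRICHROMATIC_COEFFICIENTS
    pigment = (c663 * (extract.a663 - extract.a750)
               + c645 * (extract.a645 - extract.a750)
               + c630 * (extract.a630 - extract.a750))
    chla = pigment * extract.extract_volume_ml / (
        extract.filtered_volume_l * extract.path_length_cm)
    if chla < 0:
        warnings.warn(f"negative chlorophyll-a ({chla:.4g}) floored at 0",
                      stacklevel=2)
        return 0.0
    return chla


def cell_density(count: ChamberCount) -> float:
    """Cells per litre of original (pre-concentration) water."""
    cells_per_ml = count.cells_counted / (count.fields_counted * count.field_volume_ml)
    return cells_per_ml * 1000.0 / count.concentration_factor


def _check_same_source(tables: Sequence[TaxonCountTable]) -> None:
    if not tables:
        raise ValidationError("need at least one count table")
    sources = {t.source for t in tables}
    if len(sources) > 1:
        raise ValidationError(f"mixed sources: {sorted(sources)}")


def pooled_counts(tables: Sequence[TaxonCountTable],
                  level: str = "phylum") -> Counter:
    """Pool counts over tables at phylum or genus level."""
    if level not in ("phylum", "genus"):
        raise ValidationError(f"level must be 'phylum' or 'genus', got {level!r}")
    pool: Counter = Counter()
    for t in tables:
        for r in t.rows:
            pool[r.phylum if level == "phylum" else r.genus] += r.count
    return pool


def composition(tables: Sequence[TaxonCountTable],
                level: str = "phylum") -> dict[str, float]:
    """Pooled percent contribution per taxon; sums to 100 before rounding."""
    _check_same_source(tables)
    pool = pooled_counts(tables, level)
    grand_total = sum(pool.values())
    if grand_total == 0:
        raise ValidationError("grand total of counts is zero")
    return {taxon: 100.0 * n / grand_total for taxon, n in pool.items()}


def simpson(tables: TaxonCountTable | Sequence[TaxonCountTable]) -> DiversityResult:
    """Simpson index D = sum n(n-1) / (N(N-1)) over genus-level counts.

    Exact integer arithmetic; the reciprocal is computed from the unrounded
    D and is undefined (None) when D = 0.
    """
    if isinstance(tables, TaxonCountTable):
        tables = [tables]
    pool = pooled_counts(list(tables), level="genus")
    big_n = sum(pool.values())
    if big_n < 2:
        raise ValidationError(f"Simpson index undefined for N = {big_n} (< 2)")
    numerator = sum(n * (n - 1) for n in pool.values())
    d = numerator / (big_n * (big_n - 1))
    return DiversityResult(
        d=d,
        reciprocal=(1.0 / d) if d > 0 else None,
        n_taxa=sum(1 for n in pool.values() if n > 0),
        n_total=big_n,
    )


def station_median(values: Iterable[float]) -> float:
    """Median over stations (mean of the central pair for even n)."""
    values = list(values)
    if not values:
        raise ValidationError("station_median of empty sequence")
    return statistics.median(values)
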