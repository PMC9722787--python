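"""Odds-ratio diet electivity comparing gut and environmental proportions.

For a taxon with gut proportion g and environmental proportion a,

    O = (g / (1 - g)) * ((1 - a) / a)        (odds ratio)
    X = O / (1 + O)                          (logistic transform, in [0, 1])

X = 0.5 means the taxon's share is identical in gut and environment; X -> 1
as g -> 1 (strong selection) and X = 0 when g = 0 (avoidance).
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .core_io import TaxonCountTable, ValidationError
from .plankton import pooled_counts, _check_same_source

DEFAULT_SIZE_BINS = (10.0, 20.0, 30.0, 35.0)
_SIZE_LABELS = ("small", "medium", "large")


@dataclass
class ElectivityResult:
    taxon: str
    a: float
    g: float
    odds_ratio: float
    index: float
    size_class: str = "all"


def taxon_proportions(tables: Sequence[TaxonCountTable],
                      level: str = "phylum") -> dict[str, float]:
    """Pooled per-taxon proportions from tables of one source; sums to 1."""
    _check_same_source(tables)
    pool = pooled_counts(tables, level)
    grand_total = sum(pool.values())
    if grand_total == 0:
        raise ValidationError("grand total of counts is zero")
    return {taxon: n / grand_total for taxon, n in pool.items()}


def electivity_index(g: float, a: float, *, taxon: str = "",
                     size_class: str = "all") -> ElectivityResult:
    """Odds-ratio electivity of one taxon from its two proportions."""
    if not 0.0 <= g <= 1.0:
        raise ValidationError(f"gut proportion out of [0, 1]: {g!r}")
    if not 0.0 < a < 1.0:
        raise ValidationError(
            f"environmental proportion {a!r} is degenerate (must be strictly "
            "inside (0, 1); use the add-half correction for zero counts)")
    if g == 1.0:
        odds, index = math.inf, 1.0
    elif g == 0.0:
        odds, index = 0.0, 0.0
    elif g == a:
        # algebraic identity; avoids float noise around the neutral point
        odds, index = 1.0, 0.5
    else:
        odds = (g / (1.0 - g)) * ((1.0 - a) / a)
        index = odds / (1.0 + odds)
    return ElectivityResult(taxon=taxon, a=a, g=g, odds_ratio=odds,
                            index=index, size_class=size_class)


def _corrected_proportions(tables: Sequence[TaxonCountTable], level: str,
                           universe: Sequence[str],
                           correction: str) -> dict[str, float]:
    pool = pooled_counts(tables, level)
    add = 0.5 if correction == "add-half" else 0.0
    counts = {t: pool.get(t, 0) + add for t in universe}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("grand total of counts is zero")
    return {t: c / total for t, c in counts.items()}


def _assign_bin(length: float, bins: Sequence[float]) -> str | None:
    # Half-open [lo, hi) bins; the final bin is closed on the right.
    for i in range(len(bins) - 1):
        lo, hi = bins[i], bins[i + 1]
        last = i == len(bins) - 2
        if lo <= length < hi or (last and length == hi):
            if len(bins) == 4:
                return _SIZE_LABELS[i]
            return f"[{lo:g},{hi:g})" if not last else f"[{lo:g},{hi:g}]"
    return None


def electivity_profile(water: Sequence[TaxonCountTable],
                       gut: Sequence[TaxonCountTable],
                       level: str = "phylum",
                       size_bins: Sequence[float] | None = DEFAULT_SIZE_BINS,
                       correction: str = "none") -> list[ElectivityResult]:
    """Per-taxon electivity overall and, optionally, by fish size class.

    The taxon universe is the union of taxa seen in water and gut. With the
    correction off, a taxon present in guts but absent from the water pool
    raises (its environmental proportion is degenerate); ``correction =
    'add-half'`` adds 0.5 to every taxon count in both pools first.
    """
    if correction not in ("none", "add-half"):
        raise ValidationError(f"unknown correction {correction!r}")
    if not water or not gut:
        raise ValidationError("water and gut table sets must both be non-empty")
    if any(t.source != "water" for t in water):
        raise ValidationError("'water' tables must all have source 'water'")
    if any(t.source != "gut" for t in gut):
        raise ValidationError("'gut' tables must all have source 'gut'")

    water_pool = pooled_counts(water, level)
    gut_pool = pooled_counts(gut, level)
    universe = sorted(set(water_pool) | set(gut_pool))
    if correction == "none":
        orphans = [t for t in universe
                   if water_pool.get(t, 0) == 0 and gut_pool.get(t, 0) > 0]
        if orphans:
            raise ValidationError(
                f"taxa absent from the water pool: {orphans}; their "
                "environmental proportion is zero — rerun with the "
                "add-half correction")

    a = _corrected_proportions(water, level, universe, correction)

    groups: dict[str, list[TaxonCountTable]] = {"all": list(gut)}
    if size_bins is not None:
        excluded = []
        for table in gut:
            label = _assign_bin(table.fish_length_cm, size_bins)
            if label is None:
                excluded.append(table.sample_id)
                continue
            groups.setdefault(label, []).append(table)
        if excluded:
            warnings.warn(
                f"{len(excluded)} fish outside all size bins excluded: "
                f"{excluded[:5]}", stacklevel=2)

    results: list[ElectivityResult] = []
    for size_class, tables in groups.items():
        g = _corrected_proportions(tables, level, universe, correction)
        for taxon in universe:
            results.append(electivity_index(
                g[taxon], a[taxon], taxon=taxon, size_class=size_class))
    return results
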