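"""Annotate diet/community composition with literature PUFA fractions and
compute season-averaged contributions.

All averaging operates on unrounded inputs; rounding (decimal half-up, one
decimal) happens only at the reporting edge via :func:`round_half_up`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._defaults import PUFA_PERCENT
from ._util import round_half_up
from .core_io import ValidationError

#: Phyla with literature PUFA annotation (percent of total fatty acids).
ANNOTATED_PHYLA = tuple(PUFA_PERCENT)


@dataclass
class PufaTable:
    """Per-phylum PUFA share as a percent of total fatty acids."""

    percents: Mapping[str, float] = field(default_factory=lambda: dict(PUFA_PERCENT))

    def __post_init__(self) -> None:
        for phylum, pct in self.percents.items():
            if not 0.0 <= pct <= 100.0:
                raise ValidationError(
                    f"PUFA percent for {phylum!r} out of [0, 100]: {pct!r}")


def season_average_contribution(
        by_season: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Unweighted dry/wet mean percent per phylum (unrounded).

    A phylum recorded in only one season is averaged with 0 for the other
    and flagged with a warning.
    """
    for season in ("dry", "wet"):
        if season not in by_season:
            raise ValidationError(f"season {season!r} missing from composition")
    dry, wet = by_season["dry"], by_season["wet"]
    averages: dict[str, float] = {}
    for phylum in {*dry, *wet}:
        if phylum not in dry or phylum not in wet:
            warnings.warn(
                f"{phylum} present in one season only; averaged with 0",
                stacklevel=2)
        averages[phylum] = (dry.get(phylum, 0.0) + wet.get(phylum, 0.0)) / 2.0
    return averages


def combined_contribution(percents: Mapping[str, float],
                          phyla: Sequence[str]) -> float:
    """Sum of percent contributions over a phylum subset (unrounded)."""
    if not phyla:
        raise ValidationError("phylum subset is empty")
    missing = [p for p in phyla if p not in percents]
    if missing:
        raise ValidationError(f"unknown phyla: {missing}")
    return float(sum(percents[p] for p in phyla))


def pufa_weighted_score(composition: Mapping[str, float],
                        pufa: PufaTable | None = None) -> tuple[float, float]:
    """Composition-weighted PUFA percent over the annotated phyla.

    ``composition`` maps phylum to fraction or percent; shares over the
    annotated phyla are renormalised to 1 first. Returns ``(score,
    annotated_mass)`` where ``annotated_mass`` is the fraction of the input
    composition the score covers.
    """
    pufa = pufa or PufaTable()
    annotated = {p: v for p, v in composition.items() if p in pufa.percents and v > 0}
    if not annotated:
        raise ValidationError("no annotated phylum present in composition")
    total = sum(composition.values())
    mass = sum(annotated.values())
    shares = {p: v / mass for p, v in annotated.items()}
    score = sum(share * pufa.percents[p] for p, share in shares.items())
    return float(score), float(mass / total if total > 0 else 0.0)
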