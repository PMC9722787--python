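"""Descriptive tables, seasonal/spatial nonparametric tests, starred
correlation matrix, and correlation-matrix PCA of the water-quality panel.

Missing values are excluded pairwise (tests, correlations) or casewise
(PCA); nothing is imputed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core_io import (PARAMETERS, WaterSample, ValidationError,
                      samples_to_frame, DRY, WET)

#: Parameters offered to the statistical stages (panel plus derived DIN).
STAT_PARAMETERS = PARAMETERS + ("din",)

STAR_LEVELS = (0.05, 0.01, 0.001)
_STARS = {0: "none", 1: "*", 2: "**", 3: "***"}


@dataclass
class SeasonalComparison:
    parameter: str
    dry_median: float
    wet_median: float
    test: str
    statistic: float
    p_value: float
    significant_at: float | None
    n: int = 0


@dataclass
class CorrelationCell:
    pair: tuple[str, str]
    r: float
    p_value: float
    stars: str
    n: int = 0


@dataclass
class PCAResult:
    n_components_retained: int
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame
    contributions: pd.DataFrame
    scores: pd.DataFrame
    rank_deficient: bool = False


def _finest_level(p: float, levels: Sequence[float] = STAR_LEVELS) -> float | None:
    passed = [lvl for lvl in levels if p < lvl]
    return min(passed) if passed else None


def _stars_for(p: float, levels: Sequence[float] = STAR_LEVELS) -> str:
    if math.isnan(p):
        return "none"
    return _STARS[sum(p < lvl for lvl in levels)]


def descriptives(samples: Iterable[WaterSample],
                 parameters: Sequence[str] = STAT_PARAMETERS) -> pd.DataFrame:
    """Median and standard error (sd/sqrt(n)) per parameter x station x season.

    Cells with a single value get SE = NaN and a flag; empty cells are
    flagged missing.
    """
    frame = samples_to_frame(samples)
    records = []
    for parameter in parameters:
        for (station, season), group in frame.groupby(["station_id", "season"],
                                                      sort=False):
            values = group[parameter].dropna()
            n = len(values)
            if n == 0:
                records.append({"parameter": parameter, "station_id": station,
                                "season": season, "median": math.nan,
                                "se": math.nan, "n": 0, "flag": "empty"})
                continue
            se = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            records.append({"parameter": parameter, "station_id": station,
                            "season": season, "median": float(values.median()),
                            "se": se, "n": n,
                            "flag": "" if n >= 2 else "single_value"})
    return pd.DataFrame.from_records(records)


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank on matched vectors.

    Exact null for n <= 25 without zeros; otherwise the normal approximation
    with tie correction (zeros split). Identical vectors give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    has_zeros = np.any(d == 0)
    method = "approx" if (has_zeros or len(d) > 25) else "exact"
    res = _stats.wilcoxon(x, y, zero_method="zsplit", correction=False,
                          alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def seasonal_test(parameter: str, samples: Iterable[WaterSample],
                  min_pairs: int = 5) -> SeasonalComparison:
    """Paired Wilcoxon signed-rank between seasons, matched by site.

    Each site's within-season replicates are averaged first; sites observed
    in both seasons form the matched pairs.
    """
    frame = samples_to_frame(samples)
    if parameter not in frame.columns:
        raise ValidationError(f"unknown parameter {parameter!r}")
    seasonal = (frame[frame["season"].isin([DRY, WET])]
                .groupby(["site_id", "season"])[parameter].mean().unstack())
    if DRY not in seasonal.columns or WET not in seasonal.columns:
        raise ValidationError("need samples from both seasons")
    paired = seasonal[[DRY, WET]].dropna()
    if len(paired) < min_pairs:
        raise ValidationError(
            f"need >= {min_pairs} matched site pairs, got {len(paired)}")
    statistic, p = paired_wilcoxon(paired[DRY].to_numpy(), paired[WET].to_numpy())
    return SeasonalComparison(
        parameter=parameter,
        dry_median=float(paired[DRY].median()),
        wet_median=float(paired[WET].median()),
        test="wilcoxon_paired", statistic=statistic, p_value=p,
        significant_at=_finest_level(p), n=len(paired))


def spatial_test(parameter: str, samples: Iterable[WaterSample],
                 season: str | None = None) -> SeasonalComparison:
    """Kruskal-Wallis H across stations (tie-corrected, chi-square p)."""
    frame = samples_to_frame(samples)
    if parameter not in frame.columns:
        raise ValidationError(f"unknown parameter {parameter!r}")
    if season is not None:
        frame = frame[frame["season"] == season]
    groups = [g[parameter].dropna().to_numpy()
              for _, g in frame.groupby("station_id", sort=False)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValidationError("need >= 2 stations with >= 2 values each")
    statistic, p = _stats.kruskal(*groups)
    medians = [float(np.median(g)) for g in groups]
    return SeasonalComparison(
        parameter=parameter, dry_median=float(np.median(medians)),
        wet_median=math.nan, test="kruskal_wallis",
        statistic=float(statistic), p_value=float(p),
        significant_at=_finest_level(p), n=sum(len(g) for g in groups))


def correlation_matrix(samples: Iterable[WaterSample],
                       parameters: Sequence[str] = STAT_PARAMETERS,
                       star_levels: Sequence[float] = STAR_LEVELS,
                       min_pairs: int = 3) -> list[CorrelationCell]:
    """Pearson r with two-sided t-test p per parameter pair.

    Missing values are deleted pairwise; a constant parameter yields an
    undefined (NaN) r, flagged with a warning.
    """
    frame = samples_to_frame(samples)[list(parameters)]
    cells: list[CorrelationCell] = []
    for i, p1 in enumerate(parameters):
        for p2 in parameters[i:]:
            sub = frame[[p1, p2]].dropna() if p1 != p2 else frame[[p1]].dropna()
            n = len(sub)
            if p1 == p2:
                cells.append(CorrelationCell(pair=(p1, p2), r=1.0, p_value=0.0,
                                             stars="***", n=n))
                continue
            if n < min_pairs:
                raise ValidationError(
                    f"fewer than {min_pairs} complete pairs for ({p1}, {p2})")
            x, y = sub[p1].to_numpy(), sub[p2].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                warnings.warn(f"constant parameter in pair ({p1}, {p2}); "
                              "r undefined", stacklevel=2)
                cells.append(CorrelationCell(pair=(p1, p2), r=math.nan,
                                             p_value=math.nan, stars="none", n=n))
                continue
            r, p = _stats.pearsonr(x, y)
            cells.append(CorrelationCell(pair=(p1, p2), r=float(r),
                                         p_value=float(p),
                                         stars=_stars_for(p, star_levels), n=n))
    return cells


def correlation_cells_to_frame(cells: Sequence[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [{"parameter_1": c.pair[0], "parameter_2": c.pair[1], "r": c.r,
          "p_value": c.p_value, "stars": c.stars, "n": c.n} for c in cells])


def pca(samples: Iterable[WaterSample],
        parameters: Sequence[str] = STAT_PARAMETERS,
        n_components_retained: int = 4) -> PCAResult:
    """PCA on the correlation matrix of z-scored parameters.

    Deterministic sign convention: within each component the largest-
    magnitude loading is positive. Components beyond the numerical rank are
    zeroed and the result flagged.
    """
    frame = samples_to_frame(samples)
    data = frame[list(parameters)].dropna()
    n, p = data.shape
    if n < p + 1:
        raise ValidationError(
            f"need >= {p + 1} complete samples for {p} parameters, got {n}")
    X = data.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        constant = [parameters[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant parameters: {constant}")
    Z = (X - mean) / sd
    corr = Z.T @ Z / (n - 1)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]

    rank_deficient = bool(np.any(eigenvalues < 1e-10))
    eigenvalues = np.where(eigenvalues < 1e-10, 0.0, eigenvalues)

    # sign convention: largest-|loading| entry positive per component
    for j in range(p):
        pivot = np.argmax(np.abs(vectors[:, j]))
        if vectors[pivot, j] < 0:
            vectors[:, j] = -vectors[:, j]

    scores = Z @ vectors
    percent = 100.0 * eigenvalues / eigenvalues.sum()
    dims = [f"dim{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(vectors, index=list(parameters), columns=dims)
    contributions = pd.DataFrame(100.0 * vectors ** 2,
                                 index=list(parameters), columns=dims)
    score_frame = pd.DataFrame(scores, columns=dims, index=data.index)
    score_frame.insert(0, "season", frame.loc[data.index, "season"].to_numpy())
    score_frame.insert(0, "station_id", frame.loc[data.index, "station_id"].to_numpy())
    return PCAResult(
        n_components_retained=min(n_components_retained, p),
        eigenvalues=eigenvalues,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=loadings, contributions=contributions, scores=score_frame,
        rank_deficient=rank_deficient)
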