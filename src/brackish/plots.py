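"""Optional quick-look plots. Never required by the analysis stages."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core_io import CTDCast
from .electivity import ElectivityResult
from .waterstats import PCAResult


def plot_salinity_section(section: Sequence[CTDCast], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    axis = [c.axis_km for c in section]
    ax.plot(axis, [c.s_sur for c in section], "o-", label="surface")
    ax.plot(axis, [c.s_bot for c in section], "s--", label="bottom")
    ax.set_xlabel("distance seaward (km)")
    ax.set_ylabel("salinity (PSU)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_scores(result: PCAResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for season, group in result.scores.groupby("season"):
        ax.scatter(group["dim1"], group["dim2"], label=season, alpha=0.7)
    ax.set_xlabel(f"dim1 ({result.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"dim2 ({result.percent_variance[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_electivity(results: Sequence[ElectivityResult], path: str | Path) -> None:
    pooled = [r for r in results if r.size_class == "all"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([r.taxon for r in pooled], [r.index for r in pooled])
    ax.axhline(0.5, color="grey", linestyle=":")
    ax.set_ylabel("electivity index")
    ax.set_ylim(0, 1)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
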