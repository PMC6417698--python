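"""Report writers: CSV tables mirroring the survey-style layouts, and JPC plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import Metal
from .distributions import GofReport


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def ranking_frame(
    rankings: Mapping[tuple[str, Metal], Sequence[GofReport]]
) -> pd.DataFrame:
    """Flatten per-stratum goodness-of-fit rankings into one table
    (season, metal, family, KS D/p, AD A²/p, AIC, selected flag)."""
    rows = []
    for (season, metal), reports in rankings.items():
        for rank, rep in enumerate(reports):
            rows.append(
                {
                    "season": season,
                    "metal": metal.value,
                    "family": rep.family.value,
                    "ks_D": rep.ks_D,
                    "ks_p": rep.ks_p,
                    "ad_A2": rep.ad_A2,
                    "ad_p": rep.ad_p,
                    "aic": rep.aic,
                    "selected": rank == 0,
                }
            )
    return pd.DataFrame(rows)


def plot_jpc(curves, path: str | Path, title: str = "Joint probability curves") -> Path:
    """Plot one or more JPC curves (fraction of species affected vs EXP)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    if not isinstance(curves, dict):
        curves = {"": curves}
    for label, curve in curves.items():
        ax.plot(curve.grid * 100, curve.exp_values * 100, label=str(label) or None)
    ax.set_xlabel("Potentially affected fraction of species (%)")
    ax.set_ylabel("Exceedance probability of exposure (%)")
    ax.set_title(title)
    if any(str(k) for k in curves):
        ax.legend(fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
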