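"""Forest and funnel plot rendering.

Each renderer returns the coordinate table it drew from, so tests can check
the numbers without parsing image files. Figures are written with the Agg
backend (no display needed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .effect_pooling import EffectEstimate, PooledResult  # noqa: E402
from .publication_bias import FunnelData  # noqa: E402

__all__ = ["render_forest", "render_funnel"]


def render_forest(effects: list[EffectEstimate],
                  pooled: PooledResult,
                  path: Optional[str] = None,
                  title: str = "") -> pd.DataFrame:
    """Forest plot: one row per study (square at the OR, bar spanning the
    95% CI), a diamond for the pooled OR at the bottom, and a vertical
    reference line at OR = 1. Returns the coordinate table.
    """
    rows = [
        {"label": e.study_label, "or": e.odds_ratio,
         "ci_low": e.ci_low, "ci_high": e.ci_high, "kind": "study"}
        for e in effects
    ]
    rows.append({"label": f"pooled ({pooled.model.value})",
                 "or": pooled.odds_ratio, "ci_low": pooled.ci_low,
                 "ci_high": pooled.ci_high, "kind": "pooled"})
    coords = pd.DataFrame(rows)

    if path is not None:
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(coords) + 1.5))
        y_positions = range(len(coords), 0, -1)
        for y, (_, row) in zip(y_positions, coords.iterrows()):
            marker = "D" if row["kind"] == "pooled" else "s"
            ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="k", lw=1)
            ax.plot(row["or"], y, marker, color="k",
                    markersize=8 if row["kind"] == "pooled" else 5)
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_yticks(list(y_positions))
        ax.set_yticklabels(coords["label"])
        ax.set_xscale("log")
        ax.set_xlabel("Odds ratio (log scale)")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    return coords


def render_funnel(funnel: FunnelData,
                  path: Optional[str] = None,
                  title: str = "") -> pd.DataFrame:
    """Funnel plot: log OR vs its SE with the SE axis increasing downward
    and pseudo-95% guide lines. Returns the point coordinate table.
    """
    coords = pd.DataFrame(
        [{"label": p.study_label, "x": p.x, "y": p.y} for p in funnel.points]
    )
    if path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(coords["x"], coords["y"], color="k", s=18, zorder=3)
        ax.plot(funnel.guide_x_low, funnel.guide_y, "k--", lw=0.8)
        ax.plot(funnel.guide_x_high, funnel.guide_y, "k--", lw=0.8)
        ax.axvline(funnel.centre, color="k", lw=0.8)
        ax.invert_yaxis()
        ax.set_xlabel("log OR")
        ax.set_ylabel("SE of log OR")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    return coords
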