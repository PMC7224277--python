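"""Figure generators: association forest plots and variance-component bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(assoc: pd.DataFrame, path=None):
    """Mean height–education effects with 95% CIs per age group, one panel
    per sex (and per region when present)."""
    panels = (
        [((s, r), g) for (s, r), g in assoc.groupby(["sex", "region"])]
        if "region" in assoc.columns
        else [((s,), g) for s, g in assoc.groupby("sex")]
    )
    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), sharey=True, squeeze=False)
    for ax, (key, g) in zip(axes[0], panels):
        g = g.sort_values("age_group")
        x = g["age_group"].to_numpy()
        ax.errorbar(
            x, g["beta"],
            yerr=[g["beta"] - g["ci_low"], g["ci_high"] - g["beta"]],
            fmt="o", ms=3, capsize=2, lw=1,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(" / ".join(map(str, key)))
        ax.set_xlabel("age group")
    axes[0][0].set_ylabel("height difference (cm) per SD of parental education")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def variance_bars(strata: pd.DataFrame, path=None, scale: str = "raw"):
    """Stacked A / C / E bars by age group, one panel per sex × education
    category (and region when present)."""
    comp = ("A", "C", "E") if scale == "raw" else ("a2", "c2", "e2")
    colors = {"A": "0.6", "C": "0.1", "E": "1.0", "a2": "0.6", "c2": "0.1", "e2": "1.0"}
    keys = ["sex", "edu_category"] + (["region"] if "region" in strata.columns else [])
    panels = list(strata.groupby(keys))
    n = max(len(panels), 1)
    ncol = min(n, 3)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, (key, g) in zip(axes.ravel(), panels):
        g = g.sort_values("age_group")
        x = np.arange(len(g))
        bottom = np.zeros(len(g))
        for c in comp:
            ax.bar(x, g[c], bottom=bottom, color=colors[c], edgecolor="black",
                   lw=0.4, label=c)
            bottom += g[c].to_numpy()
        ax.set_xticks(x, g["age_group"].astype(int), fontsize=7)
        ax.set_title(" / ".join(map(str, key if isinstance(key, tuple) else (key,))), fontsize=9)
    axes.ravel()[0].legend(fontsize=7)
    for ax in axes.ravel()[len(panels):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
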