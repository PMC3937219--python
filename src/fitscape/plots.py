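"""Figure export: landscape heatmap/surface and phenotype-jump vectors.

All figures are regenerated from the emitted tables, so every plotted
number is inspectable; nothing is computed only for display.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .geometry import global_optimum, gradient_at
from .landscape import LandscapeParameters, corrected_surface

__all__ = ["landscape_heatmap", "jump_vectors", "standard_figures"]


def landscape_heatmap(params: LandscapeParameters, p_ref: float,
                      path, domain=((1, 150), (1, 150)),
                      strains: pd.DataFrame | None = None,
                      scale: np.ndarray | None = None) -> Path:
    """Heatmap of the plasmid-cost-corrected surface, data overlaid."""
    (a_lo, a_hi), (g_lo, g_hi) = domain
    flha = np.linspace(a_lo, a_hi, 200)
    fgha = np.linspace(g_lo, g_hi, 200)
    F, G, W, peak = corrected_surface(params, p_ref, flha, fgha)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(F, G, W, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="predicted fitness W")
    ax.plot(peak["flha"], peak["fgha"], "r^", label="surface maximum")
    if strains is not None:
        sc = np.ones(2) if scale is None else scale
        markers = {"ancestor": ("*", "white"), "single_A": ("o", "0.7"),
                   "single_B": ("o", "0.4"), "combination": ("s", "white"),
                   "inducible": ("o", "black")}
        for cat, (m, c) in markers.items():
            sub = strains[strains["category"] == cat]
            if len(sub):
                ax.scatter(sub["flha_obs"] * sc[0], sub["fgha_obs"] * sc[1],
                           marker=m, facecolors=c, edgecolors="k",
                           s=40, label=cat)
    ax.set_xlabel("FlhA level (ancestor = 100)")
    ax.set_ylabel("FghA level (ancestor = 100)")
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def jump_vectors(strains: pd.DataFrame, params: LandscapeParameters,
                 p_ref: float, path, domain=((1, 150), (1, 150)),
                 scale: np.ndarray | None = None) -> Path:
    """Single-mutant phenotype displacements vs the reference vectors."""
    sc = np.ones(2) if scale is None else scale
    anc = np.array([100.0, 100.0])
    fig, ax = plt.subplots(figsize=(6, 5))
    singles = strains[strains["category"].isin(["single_A", "single_B"])]
    for _, row in singles.iterrows():
        mut = np.array([row["flha_obs"] * sc[0], row["fgha_obs"] * sc[1]])
        ax.annotate("", xy=mut, xytext=anc,
                    arrowprops=dict(arrowstyle="->", color="red"))
        ax.text(*mut, row["strain"], fontsize=7)

    def ref_arrow(vec, color, label, length=60.0):
        v = np.asarray(vec, dtype=float)
        v = v / np.linalg.norm(v) * length
        ax.annotate("", xy=anc + v, xytext=anc,
                    arrowprops=dict(arrowstyle="->", color=color, lw=2))
        ax.plot([], [], color=color, label=label)

    ref_arrow(gradient_at(anc, params, p_ref), "blue", "local gradient")
    opt = np.array(global_optimum(params, domain, p_ref).point)
    ref_arrow(opt - anc, "green", "to global optimum")
    ref_arrow((-1, -1), "black", "1:1 proportional change")
    ax.plot(*anc, "k*", markersize=12)
    ax.set_xlabel("FlhA level (ancestor = 100)")
    ax.set_ylabel("FghA level (ancestor = 100)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def standard_figures(strains, lfit, rel_params, domain, p_ref, outdir
                     ) -> dict[str, Path]:
    outdir = Path(outdir)
    anc = strains[strains["category"] == "ancestor"].iloc[0]
    scale = np.array([100.0 / anc["flha_obs"], 100.0 / anc["fgha_obs"]])
    return {
        "fig_landscape": landscape_heatmap(
            rel_params, p_ref, outdir / "landscape_heatmap.png",
            domain, strains, scale),
        "fig_vectors": jump_vectors(
            strains, rel_params, p_ref, outdir / "jump_vectors.png",
            domain, scale),
    }
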