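"""Heat-map rendering of fit surfaces.

One figure per search round: small rectangles coloured by AND value,
arranged as start-size x end-size panels tiled by expansion end time
(columns) and expansion duration (rows).  Red marks a good fit, blue a
poor one; cells excluded by the TMRCA-compatibility filter are grey, and
accepted cells (AND below the cutoff) are dotted.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .inference import AND_CUTOFF, FitSurface, ParamGrid

__all__ = ["plot_fit_surface"]


def plot_fit_surface(
    surface: FitSurface,
    grid: ParamGrid,
    path,
    cutoff: float = AND_CUTOFF,
    vmax: float | None = None,
):
    """Render one round's AND surface to ``path`` (PNG/PDF by extension)."""
    t_vals = grid.axes["t_end_years"]
    d_vals = grid.axes["duration_years"]
    s_vals = grid.axes["start_n"]
    e_vals = grid.axes["end_n"]
    tab = surface.table
    if vmax is None:
        finite = tab["and_value"][np.isfinite(tab["and_value"])]
        vmax = float(finite.quantile(0.95)) if len(finite) else 1.0
    fig, axes = plt.subplots(
        len(d_vals), len(t_vals),
        figsize=(2.0 * len(t_vals) + 1.5, 1.8 * len(d_vals) + 1.0),
        squeeze=False,
    )
    cmap = plt.get_cmap("RdYlBu")
    for i, dv in enumerate(d_vals):
        for j, tv in enumerate(t_vals):
            ax = axes[i][j]
            sub = tab[(tab["duration_years"] == dv) & (tab["t_end_years"] == tv)]
            img = np.full((len(e_vals), len(s_vals)), np.nan)
            for _, row in sub.iterrows():
                si = int(np.searchsorted(s_vals, row["start_n"]))
                ei = int(np.searchsorted(e_vals, row["end_n"]))
                img[ei, si] = row["and_value"] if not row["excluded"] else np.nan
            cmap.set_bad("0.8")
            ax.imshow(
                img, origin="lower", aspect="auto", cmap=cmap, vmin=0, vmax=vmax
            )
            for _, row in sub.iterrows():
                if not row["excluded"] and row["and_value"] < cutoff:
                    si = int(np.searchsorted(s_vals, row["start_n"]))
                    ei = int(np.searchsorted(e_vals, row["end_n"]))
                    ax.plot(si, ei, "k.", ms=4)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(f"end {tv / 1000:.1f} KYA", fontsize=7)
            if j == len(t_vals) - 1:
                ax.yaxis.set_label_position("right")
                ax.set_ylabel(f"{dv / 1000:.2f} KY", fontsize=7, rotation=270,
                              labelpad=10)
            if j == 0:
                ax.set_ylabel("EndN", fontsize=6)
            if i == len(d_vals) - 1:
                ax.set_xlabel("StartN", fontsize=6)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, vmax))
    fig.colorbar(sm, ax=axes, shrink=0.6, label="AND")
    fig.suptitle(f"round {surface.round_index}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
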