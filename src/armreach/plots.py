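"""Figure generation: error contour maps, failure-fraction bars,
co-activation heatmaps.  Every figure writes its gridded values to CSV
alongside so plots are regenerable without re-simulating."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LogNorm

#: co-activation histogram bin edges (dimensionless activation level)
COACT_BINS = np.concatenate([[0.0], np.logspace(-3, 0, 16)])


def render_error_map(summary: pd.DataFrame, error_field: str,
                     boundary=None, out_prefix: str | Path = "error_map",
                     floor_mm: float = 1e-3):
    """Log-scaled contour map of e_h or e_mv over the rectangular grid.

    ``summary`` must come from a rect_grid run (regular x/y lattice);
    out-of-workspace targets are still plotted.  Writes <prefix>.png and
    <prefix>.csv; returns the matplotlib figure.
    """
    if error_field not in summary.columns:
        raise ValueError(f"unknown error field {error_field!r}")
    xs = np.sort(summary["x"].unique())
    ys = np.sort(summary["y"].unique())
    if len(xs) * len(ys) != len(summary):
        raise ValueError("summary is not a rectangular grid")
    piv = summary.pivot(index="y", columns="x", values=error_field)
    Z = np.clip(piv.to_numpy(float), floor_mm, None)
    fig, ax = plt.subplots(figsize=(6, 5))
    levels = np.logspace(np.log10(floor_mm), max(np.log10(np.nanmax(Z)), 0.1), 12)
    cs = ax.contourf(piv.columns, piv.index, Z, levels=levels,
                     norm=LogNorm(), cmap="viridis")
    fig.colorbar(cs, ax=ax, label=f"{error_field} (mm, log scale)")
    if boundary is not None:
        bx, by = boundary.exterior.xy
        ax.plot(bx, by, "k--", lw=1)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    out_prefix = Path(out_prefix)
    summary[["x", "y", error_field]].to_csv(out_prefix.with_suffix(".csv"), index=False)
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150, bbox_inches="tight")
    return fig


def coactivation_distribution(summaries: dict[str, pd.DataFrame],
                              joint: str = "shoulder",
                              bins: np.ndarray = COACT_BINS) -> pd.DataFrame:
    """Rows = scenario label, columns = co-activation bins, values =
    fraction of in-workspace targets in the bin (each row sums to 1)."""
    col = f"coact_{joint}"
    rows = {}
    for label, df in summaries.items():
        vals = df.loc[df["in_workspace"], col].to_numpy(float)
        hist, _ = np.histogram(np.clip(vals, bins[0], bins[-1]), bins=bins)
        rows[label] = hist / max(len(vals), 1)
    out = pd.DataFrame(rows).T
    out.columns = [f"bin_{lo:.4g}_{hi:.4g}" for lo, hi in zip(bins[:-1], bins[1:])]
    return out


def render_coactivation_heatmap(summaries: dict[str, pd.DataFrame],
                                joint: str = "shoulder",
                                out_prefix: str | Path = "coact_heatmap"):
    """Heatmap of co-activation distributions across scenarios (log colour
    scale); writes <prefix>.png, <prefix>.csv and <prefix>_bins.csv."""
    dist = coactivation_distribution(summaries, joint)
    fig, ax = plt.subplots(figsize=(8, 4))
    Z = np.clip(dist.to_numpy(float), 1e-4, None)
    im = ax.imshow(Z, aspect="auto", norm=LogNorm(vmin=1e-4, vmax=1.0),
                   cmap="magma")
    ax.set_yticks(range(len(dist.index)), dist.index)
    ax.set_xlabel("co-activation bin")
    ax.set_ylabel("scenario")
    fig.colorbar(im, ax=ax, label="fraction of targets (log scale)")
    out_prefix = Path(out_prefix)
    dist.to_csv(out_prefix.with_suffix(".csv"))
    pd.DataFrame({"bin_edges": COACT_BINS}).to_csv(
        out_prefix.parent / (out_prefix.name + "_bins.csv"), index=False)
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150, bbox_inches="tight")
    return fig


def render_failure_fractions(table: pd.DataFrame,
                             out_prefix: str | Path = "failure_fractions"):
    """Bar chart of boundary failure fractions.

    ``table`` columns: scenario, side, threshold_mm, control, fraction.
    """
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey="row")
    for i, thr in enumerate(sorted(table["threshold_mm"].unique(), reverse=True)):
        for j, side in enumerate(["left", "right"]):
            ax = axes[i, j]
            sub = table[(table["threshold_mm"] == thr) & (table["side"] == side)]
            for ctrl, color in (("baseline", "tab:blue"), ("retuned", "tab:red")):
                s = sub[sub["control"] == ctrl]
                if len(s):
                    ax.bar(s["scenario"], s["fraction"], color=color, alpha=0.6,
                           label=ctrl)
            ax.set_title(f"{side} boundary, e_h > {thr} mm")
            ax.set_ylim(0, 1)
    axes[0, 0].legend()
    out_prefix = Path(out_prefix)
    table.to_csv(out_prefix.with_suffix(".csv"), index=False)
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150, bbox_inches="tight")
    return fig
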