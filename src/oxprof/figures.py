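"""Presentation-only figure rendering from pipeline CSV output.

No numbers originate here: every plot re-reads tables written by the
pipeline.  Missing tables skip the figure with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from oxprof import panel
from oxprof.cohort_stats import confidence_ellipse
from oxprof.errors import DataError

logger = logging.getLogger("oxprof")

BIN_WIDTH = 0.1


def zscore_bins(values: np.ndarray, width: float = BIN_WIDTH) -> np.ndarray:
    """Histogram bin edges at a fixed width aligned to the data range."""
    lo = np.floor(values.min() / width) * width
    n = int(np.ceil((values.max() - lo) / width)) or 1
    return lo + width * np.arange(n + 1)


def _ellipse_xy(spec, n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0, 2 * np.pi, n_points)
    a, b = spec.semi_axes
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(spec.angle_rad), np.sin(spec.angle_rad)
    return spec.center[0] + ca * x - sa * y, spec.center[1] + sa * x + ca * y


def plot_z_histograms(zscores: pd.DataFrame, outdir: Path) -> list[Path]:
    paths = []
    zcols = [c for c in zscores.columns if c.startswith("z_")]
    for zcol in zcols:
        fig, ax = plt.subplots(figsize=(6, 4))
        values = zscores[zcol].dropna()
        if values.empty:
            plt.close(fig)
            continue
        bins = zscore_bins(values.to_numpy())
        for group, sub in zscores.groupby("group", sort=False):
            v = sub[zcol].dropna().to_numpy()
            if len(v) == 0:
                continue
            ax.hist(v, bins=bins, alpha=0.45, label=f"{group} (n={len(v)})")
            ax.axvline(v.mean(), linestyle="--", linewidth=1)
            if len(v) > 1 and v.std() > 0:
                grid = np.linspace(bins[0], bins[-1], 200)
                # gaussian KDE-style density curve scaled to counts
                from scipy.stats import gaussian_kde

                dens = gaussian_kde(v)(grid) * len(v) * BIN_WIDTH
                ax.plot(grid, dens, linewidth=1.2)
        ax.set_xlabel(zcol)
        ax.set_ylabel("neurons")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"hist_{zcol}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_scatter_ellipse(
    zscores: pd.DataFrame,
    outdir: Path,
    x_col: str = "z_NDUFB8",
    y_col: str = "z_MTCO1",
) -> Path | None:
    if x_col not in zscores.columns or y_col not in zscores.columns:
        logger.warning("scatter skipped: %s/%s not in zscores", x_col, y_col)
        return None
    fig, ax = plt.subplots(figsize=(5, 5))
    for group, sub in zscores.groupby("group", sort=False):
        pts = sub[[x_col, y_col]].dropna().to_numpy()
        if len(pts) == 0:
            continue
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6, label=group)
        if len(pts) >= 3:
            try:
                spec = confidence_ellipse(pts, 0.95)
            except DataError:
                continue
            ex, ey = _ellipse_xy(spec)
            ax.plot(ex, ey, linewidth=1.2)
    ax.axhline(0, color="grey", linewidth=0.5)
    ax.axvline(0, color="grey", linewidth=0.5)
    ax.set_xlabel(x_col)
    ax.set_ylabel(y_col)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "scatter_ellipse.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_pct_heatmap(case_summary: pd.DataFrame, outdir: Path) -> Path:
    pct_cols = [
        c
        for c in case_summary.columns
        if c.startswith("pct_") and not c.startswith("pct_category_")
    ]
    mat = case_summary.set_index("case_id")[pct_cols]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(mat) + 1.5))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(pct_cols)))
    ax.set_xticklabels([c[4:] for c in pct_cols], rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(mat)))
    ax.set_yticklabels(mat.index, fontsize=7)
    fig.colorbar(im, label="% decreased")
    fig.tight_layout()
    path = outdir / "heatmap_pct_decreased.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_severity_stack(stack: pd.DataFrame, outdir: Path) -> Path:
    groups = stack["group"].unique()
    fig, ax = plt.subplots(figsize=(6, 4))
    bottoms = {g: 0.0 for g in groups}
    xs = np.arange(len(groups))
    cmap = plt.get_cmap("viridis")
    for k in range(6):
        heights = [
            float(
                stack.loc[(stack["group"] == g) & (stack["category"] == k),
                          "pct_neurons"].sum()
            )
            for g in groups
        ]
        ax.bar(
            xs,
            heights,
            bottom=[bottoms[g] for g in groups],
            color=cmap(k / 5),
            label=f"{k}",
        )
        for g, h in zip(groups, heights):
            bottoms[g] += h
    ax.set_xticks(xs)
    ax.set_xticklabels(groups)
    ax.set_ylabel("% of neurons")
    ax.legend(title="complexes decreased", fontsize=8)
    fig.tight_layout()
    path = outdir / "severity_stack.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_figures(outdir) -> list[Path]:
    """Render every figure whose source table exists under ``outdir``."""
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    made: list[Path] = []

    z_path = outdir / "zscores.csv"
    if z_path.exists():
        zscores = pd.read_csv(z_path)
        made += plot_z_histograms(zscores, figdir)
        p = plot_scatter_ellipse(zscores, figdir)
        if p:
            made.append(p)
    else:
        logger.warning("zscores.csv missing: histograms and scatter skipped")

    cs_path = outdir / "case_summary.csv"
    if cs_path.exists():
        made.append(plot_pct_heatmap(pd.read_csv(cs_path), figdir))
    else:
        logger.warning("case_summary.csv missing: heatmap skipped")

    st_path = outdir / "severity_stack.csv"
    if st_path.exists():
        made.append(plot_severity_stack(pd.read_csv(st_path), figdir))
    else:
        logger.warning("severity_stack.csv missing: stacked bars skipped")
    return made
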