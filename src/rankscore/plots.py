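"""Diagnostic plots: rank barcode/density, score landscape, score vs dispersion.

Every plot function writes a static figure (PNG or SVG by default; HTML via a
minimal embedded-SVG wrapper) and returns the table of plotted coordinates so
tests can make assertions on data rather than pixels.
"""
from __future__ import annotations

import base64
import io as _io
from pathlib import Path

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from scipy.stats import gaussian_kde, spearmanr  # noqa: E402

from .errors import ValidationError  # noqa: E402
from .io import GeneSignature  # noqa: E402
from .scoring import RankProfile  # noqa: E402

__all__ = ["plot_barcode_density", "plot_landscape", "plot_score_dispersion"]

_FORMATS = ("png", "svg", "html")


def _save(fig, output_path: str | Path, fmt: str) -> Path:
    output_path = Path(output_path)
    if fmt not in _FORMATS:
        raise ValidationError(f"format must be one of {_FORMATS}, got {fmt!r}")
    output_path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "html":
        buf = _io.BytesIO()
        fig.savefig(buf, format="svg", bbox_inches="tight")
        payload = base64.b64encode(buf.getvalue()).decode()
        output_path.write_text(
            "<html><body><img src='data:image/svg+xml;base64,"
            f"{payload}'/></body></html>"
        )
    else:
        fig.savefig(output_path, format=fmt, bbox_inches="tight")
    plt.close(fig)
    return output_path


def _density(ranks: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if ranks.size < 2 or np.ptp(ranks) == 0:
        return np.full_like(grid, np.nan, dtype=float)
    return gaussian_kde(ranks)(grid)  # scipy's default (Scott) bandwidth


def plot_barcode_density(
    rp: RankProfile,
    sig: GeneSignature,
    output_path: str | Path,
    fmt: str = "png",
    percentile: bool = False,
) -> pd.DataFrame:
    """Barcode of signature-gene ranks with overlaid rank densities.

    The x-axis is the within-sample rank (1..N_total) by default, or the
    percentile rank with ``percentile=True``.  Returns the plotted table with
    one row per (gene, set) plus density-curve rows.
    """
    sets = {}
    if sig.up_genes:
        sets["up" if sig.mode != "undirected" else "undirected"] = rp.ranks_of(sig.up_genes)
    if sig.down_genes:
        sets["down"] = rp.ranks_of(sig.down_genes)
    sets = {k: v for k, v in sets.items() if v.size}
    if not sets:
        raise ValidationError(f"no genes of {sig.name!r} present in {rp.sample_id!r}")

    scale = 100.0 / rp.n_total if percentile else 1.0
    xmax = 100.0 if percentile else rp.n_total
    grid = np.linspace(1 * scale, xmax, 200)

    fig, (ax_d, ax_b) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 3.5), height_ratios=[3, 1]
    )
    rows = []
    colors = {"up": "tab:green", "down": "tab:purple", "undirected": "tab:blue"}
    for which, ranks in sets.items():
        x = ranks * scale
        dens = _density(x, grid)
        ax_d.plot(grid, dens, color=colors[which], label=which)
        for xi in x:
            rows.append({"element": "barcode", "set": which, "x": float(xi),
                         "density": np.nan})
        for gx, gy in zip(grid, dens):
            rows.append({"element": "density", "set": which, "x": float(gx),
                         "density": float(gy)})
        ax_b.vlines(x, *{"up": (0.5, 1.0), "down": (0.0, 0.5),
                         "undirected": (0.0, 1.0)}[which],
                    color=colors[which], lw=0.6)
    ax_d.set_ylabel("density")
    ax_d.legend(frameon=False, fontsize=8)
    ax_b.set_xlabel("percentile" if percentile else "rank")
    ax_b.set_yticks([])
    ax_d.set_title(f"{sig.name} in {rp.sample_id}", fontsize=9)
    fig.text(0.99, 0.01, "bw=scott", ha="right", fontsize=6, color="grey")
    _save(fig, output_path, fmt)
    return pd.DataFrame(rows, columns=["element", "set", "x", "density"])


def plot_landscape(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    output_path: str | Path,
    fmt: str = "png",
    hexbin_threshold: int = 200,
    groups: pd.Series | None = None,
    overlay: pd.DataFrame | None = None,
    overlay_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """2-D landscape of one signature's scores against another's.

    ``scores_a``/``scores_b`` are score tables with ``sample_id`` and
    ``total_score`` columns sharing sample ids.  Cohorts larger than
    ``hexbin_threshold`` are drawn as a binned density layer; an optional
    small cohort (``overlay``/``overlay_b``) is drawn as markers on top.
    Returns the plotted table with a ``layer`` column.
    """
    merged = scores_a.merge(scores_b, on="sample_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValidationError("score tables share no sample ids")
    x = merged["total_score_a"].to_numpy()
    y = merged["total_score_b"].to_numpy()
    layer = "hexbin" if len(merged) > hexbin_threshold else "markers"

    fig, ax = plt.subplots(figsize=(5, 4.5))
    if layer == "hexbin":
        ax.hexbin(x, y, gridsize=30, cmap="Greys", mincnt=1)
    else:
        if groups is not None:
            cats = groups.reindex(merged["sample_id"]).astype("category")
            ax.scatter(x, y, c=cats.cat.codes.to_numpy(), cmap="tab10", s=18,
                       edgecolor="k", lw=0.3)
        else:
            ax.scatter(x, y, s=18, edgecolor="k", lw=0.3)
    table = pd.DataFrame({
        "layer": layer, "sample_id": merged["sample_id"],
        "x": x, "y": y,
    })
    if overlay is not None:
        if overlay_b is None:
            raise ValidationError("overlay requires both score tables")
        om = overlay.merge(overlay_b, on="sample_id", suffixes=("_a", "_b"))
        ax.scatter(om["total_score_a"], om["total_score_b"], s=30,
                   facecolor="tab:red", edgecolor="k", lw=0.4, zorder=3)
        table = pd.concat([table, pd.DataFrame({
            "layer": "markers", "sample_id": om["sample_id"],
            "x": om["total_score_a"], "y": om["total_score_b"],
        })], ignore_index=True)
    ax.set_xlabel("signature A score")
    ax.set_ylabel("signature B score")
    _save(fig, output_path, fmt)
    return table


def plot_score_dispersion(
    scores: pd.DataFrame, output_path: str | Path, fmt: str = "png"
) -> pd.DataFrame:
    """Three panels: total/up/down score against its MAD rank dispersion.

    ``scores`` must carry the dispersion columns produced by
    ``score_matrix(..., dispersion=True)``.
    """
    if scores.empty:
        raise ValidationError("empty score table")
    needed = {"mad_total", "mad_up", "mad_down"}
    missing = needed - set(scores.columns)
    if missing:
        raise ValidationError(f"missing dispersion columns: {sorted(missing)}")

    panels = [
        ("total", "total_score", "mad_total"),
        ("up", "score_up", "mad_up"),
        ("down", "score_down", "mad_down"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.3))
    rows = []
    for ax, (name, score_col, mad_col) in zip(axes, panels):
        sub = scores[[score_col, mad_col]].dropna()
        x = sub[score_col].to_numpy(dtype=float)
        y = sub[mad_col].to_numpy(dtype=float)
        ax.scatter(x, y, s=12, alpha=0.7)
        if x.size >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            rho = spearmanr(x, y).statistic
            ax.set_title(f"{name} (rho={rho:.2f})", fontsize=9)
        else:
            ax.set_title(name, fontsize=9)
        ax.set_xlabel(f"{name} score")
        ax.set_ylabel("MAD of ranks")
        for xi, yi in zip(x, y):
            rows.append({"panel": name, "score": float(xi), "mad": float(yi)})
    fig.tight_layout()
    _save(fig, output_path, fmt)
    return pd.DataFrame(rows, columns=["panel", "score", "mad"])
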