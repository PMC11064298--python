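"""Figures over a finished report bundle.

All plots read the flat TSVs a run leaves behind, so they can be redrawn
without recomputing anything.  Empty inputs give labeled empty axes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from . import io


def plot_coverage_scatter(summary: pd.DataFrame, lengths: dict[str, int], ax=None):
    """Per-chromosome log2 M:F against chromosome length, with dashed
    expectation lines at 0 (autosomes) and 1 (Z)."""
    ax = ax or plt.gca()
    ax.axhline(0.0, ls="--", color="grey", lw=1, label="autosome expectation")
    ax.axhline(1.0, ls="--", color="red", lw=1, label="Z expectation")
    if len(summary):
        x = [lengths.get(c, 0) / 1e6 for c in summary.index]
        ax.scatter(x, summary["log2_mf"], s=25, c="steelblue")
        for c, xi, yi in zip(summary.index, x, summary["log2_mf"]):
            ax.annotate(c, (xi, yi), fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("chromosome length (Mb)")
    ax.set_ylabel("log2 M:F coverage")
    ax.legend(fontsize=7)
    return ax


def plot_windowed_tracks(windows: pd.DataFrame, ax=None):
    """Windowed log2 M:F tracks, one line per chromosome."""
    ax = ax or plt.gca()
    if len(windows):
        for chrom, sub in windows.groupby("chrom"):
            ax.plot(sub["start"] / 1e3, sub["log2_mf"], lw=0.8, label=chrom)
        ax.legend(fontsize=7)
    ax.set_xlabel("position (kb)")
    ax.set_ylabel("log2 M:F coverage")
    return ax


def plot_ds_density(ds: pd.DataFrame, ax=None, *, bins: int = 30, max_ds: float = 3.0):
    """Density of retained dS values (saturated/undefined pairs excluded)."""
    ax = ax or plt.gca()
    vals = []
    if len(ds) and "dS" in ds.columns:
        keep = ds[~ds["saturated"].fillna(True) & ds["dS"].notna()]
        vals = keep["dS"].tolist()
    if vals:
        ax.hist(vals, bins=bins, range=(0, max_ds), density=True, color="steelblue")
    ax.set_xlabel("dS")
    ax.set_ylabel("density")
    return ax


def plot_ds_along_w(track: pd.DataFrame, ax=None):
    """dS of each retained pair at its W-chromosome position."""
    ax = ax or plt.gca()
    if len(track):
        ax.scatter(track["position"] / 1e3, track["dS"], s=12, c="firebrick")
    ax.set_xlabel("W position (kb)")
    ax.set_ylabel("dS")
    return ax


def plot_copy_number(counts: pd.DataFrame, ax=None):
    """W vs Z/autosome copy counts per retained symbol (jittered)."""
    ax = ax or plt.gca()
    if len(counts):
        ax.scatter(counts["other_copies"], counts["w_copies"], s=15, alpha=0.6)
    ax.set_xlabel("Z/autosome copies")
    ax.set_ylabel("W copies")
    return ax


def plot_outputs(bundle_dir: str | Path, figure_dir: str | Path | None = None) -> list[Path]:
    """Draw every figure the bundle supports; returns the written paths."""
    bundle = Path(bundle_dir)
    figdir = Path(figure_dir) if figure_dir else bundle / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(name: str) -> None:
        p = figdir / name
        plt.tight_layout()
        plt.savefig(p, dpi=120)
        plt.close()
        written.append(p)

    summary_path = bundle / "coverage_summary.tsv"
    if summary_path.exists():
        summary = io.read_tsv(summary_path, index_col="chrom")
        lengths = {}
        if (bundle / "genome.fa").exists():
            lengths = {k: len(v) for k, v in io.read_fasta(bundle / "genome.fa").items()}
        plt.figure(figsize=(5, 4))
        plot_coverage_scatter(summary, lengths)
        save("coverage_scatter.png")
    windows_path = bundle / "windows.tsv"
    if windows_path.exists():
        plt.figure(figsize=(6, 3))
        plot_windowed_tracks(io.read_tsv(windows_path))
        save("windowed_ratio.png")
    ds_path = bundle / "ds_estimates.tsv"
    if ds_path.exists():
        plt.figure(figsize=(5, 3))
        plot_ds_density(io.read_tsv(ds_path))
        save("ds_density.png")
    track_path = bundle / "ds_track.tsv"
    if track_path.exists():
        plt.figure(figsize=(6, 3))
        plot_ds_along_w(io.read_tsv(track_path))
        save("ds_along_w.png")
    cn_path = bundle / "copy_number.tsv"
    if cn_path.exists():
        plt.figure(figsize=(4, 4))
        plot_copy_number(io.read_tsv(cn_path))
        save("copy_number.png")
    return written
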