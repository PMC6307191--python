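"""Human-readable summary figures, regenerated purely from the stage tables.

The report stage reads only TSV/JSON outputs written by earlier stages (never
raw volumes), so figures can be rebuilt after raw data are discarded.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

GROUP_COLORS = {"LVCP": "#c44e52", "HVCP": "#4c72b0", "NT": "#55a868"}


def _savefig(fig, path: Path) -> Path:
    fig.savefig(path, dpi=110, metadata={"Software": "fcpipe"})
    plt.close(fig)
    return path


def _motion_figure(out: Path, fig_dir: Path) -> Path | None:
    usability_path = out / "preprocess" / "usability.json"
    if not usability_path.exists():
        return None
    usability = json.loads(usability_path.read_text())
    sids = sorted(usability, key=lambda s: (usability[s]["group"], s))
    kept = [usability[s]["n_motion_free"] for s in sids]
    colors = [GROUP_COLORS[usability[s]["group"]] for s in sids]
    fig, ax = plt.subplots(figsize=(max(6, len(sids) * 0.18), 3.2))
    ax.bar(range(len(sids)), kept, color=colors)
    ax.set_xlabel("subject")
    ax.set_ylabel("motion-free volumes")
    ax.set_title("Motion-free volumes per subject")
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in GROUP_COLORS.values()]
    ax.legend(handles, GROUP_COLORS.keys(), fontsize=8)
    return _savefig(fig, fig_dir / "motion_volumes.png")


def _within_network_figure(stats_dir: Path, design: pd.DataFrame, stream: str, fig_dir: Path):
    path = stats_dir / f"{stream}_within_network.tsv"
    if not path.exists():
        return None
    table = pd.read_csv(path, sep="\t")
    fig, ax = plt.subplots(figsize=(8, 3.2))
    x = np.arange(len(table))
    width = 0.25
    for k, g in enumerate(GROUP_COLORS):
        ax.bar(x + (k - 1) * width, table[f"mean_{g}"], width, color=GROUP_COLORS[g], label=g)
    for i, row in table.iterrows():
        if row["significant"]:
            top = max(row["mean_LVCP"], row["mean_HVCP"], row["mean_NT"])
            ax.text(i, top * 1.05, "*", ha="center", fontsize=14)
    ax.set_xticks(x)
    ax.set_xticklabels(table["effect"], rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("mean within-network z")
    ax.set_title(f"Within-network connectivity by group ({stream})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _savefig(fig, fig_dir / f"{stream}_within_network.png")


def _between_network_figure(stats_dir: Path, stream: str, fig_dir: Path):
    path = stats_dir / f"{stream}_between_network_lvcp_vs_nt.tsv"
    if not path.exists():
        return None
    table = pd.read_csv(path, sep="\t")
    nets = sorted({n for eff in table["effect"] for n in eff.split("~")})
    idx = {n: i for i, n in enumerate(nets)}
    mat = np.full((len(nets), len(nets)), np.nan)
    flags = np.zeros_like(mat, dtype=bool)
    for _, row in table.iterrows():
        a, b = row["effect"].split("~")
        i, j = idx[a], idx[b]
        mat[i, j] = mat[j, i] = row["statistic"]
        flags[i, j] = flags[j, i] = bool(row["significant"])
    fig, ax = plt.subplots(figsize=(4.6, 4))
    vmax = np.nanmax(np.abs(mat)) or 1.0
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    for i in range(len(nets)):
        for j in range(len(nets)):
            if flags[i, j]:
                ax.text(j, i, "*", ha="center", va="center", fontsize=12)
    ax.set_xticks(range(len(nets)))
    ax.set_xticklabels(nets, rotation=90, fontsize=7)
    ax.set_yticks(range(len(nets)))
    ax.set_yticklabels(nets, fontsize=7)
    fig.colorbar(im, label="t (LVCP vs NT)")
    ax.set_title(f"Between-network synchrony ({stream})", fontsize=9)
    fig.tight_layout()
    return _savefig(fig, fig_dir / f"{stream}_between_network.png")


def _homotopic_figure(stats_dir: Path, stream: str, fig_dir: Path):
    made = None
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    found = False
    for ax, contrast in zip(axes, ("lvcp_vs_hvcp", "lvcp_vs_nt")):
        path = stats_dir / f"{stream}_homotopic_{contrast}.tsv"
        if not path.exists():
            continue
        found = True
        table = pd.read_csv(path, sep="\t")
        t = table["statistic"].to_numpy()
        bins = np.linspace(min(-4, t.min()), max(4, t.max()), 25)
        ax.hist(t[~table["significant"]], bins=bins, color="gray", label="n.s.")
        ax.hist(t[table["significant"]], bins=bins, color="#c44e52", label="FDR q<0.05")
        ax.set_title(contrast.replace("_", " ").upper(), fontsize=9)
        ax.set_xlabel("t statistic")
        ax.legend(fontsize=7)
    if found:
        axes[0].set_ylabel("homotopic pairs")
        fig.tight_layout()
        made = _savefig(fig, fig_dir / f"{stream}_homotopic_hist.png")
    else:
        plt.close(fig)
    return made


def _iq_figure(stats_dir: Path, stream: str, fig_dir: Path):
    path = stats_dir / f"{stream}_iq_pair_correlation.tsv"
    if not path.exists():
        return None
    mat = np.loadtxt(path, delimiter="\t")
    fig, ax = plt.subplots(figsize=(4.4, 4))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, label="r(IQ, z)")
    ax.set_title("IQ vs pairwise connectivity (LVCP)", fontsize=9)
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    fig.tight_layout()
    return _savefig(fig, fig_dir / "iq_pair_correlation.png")


def make_report(out_dir) -> list[Path]:
    """Render all figures from the tables under ``out_dir``; returns paths."""
    out = Path(out_dir)
    stats_dir = out / "stats"
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    design_path = out / "preprocess" / "design.tsv"
    design = (
        pd.read_csv(design_path, sep="\t") if design_path.exists() else pd.DataFrame()
    )
    figures = []
    fig = _motion_figure(out, fig_dir)
    if fig:
        figures.append(fig)
    for stream in ("nogsr", "gsr"):
        for fig in (
            _within_network_figure(stats_dir, design, stream, fig_dir),
            _between_network_figure(stats_dir, stream, fig_dir),
            _homotopic_figure(stats_dir, stream, fig_dir),
            _iq_figure(stats_dir, stream, fig_dir),
        ):
            if fig:
                figures.append(fig)
    return figures
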