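#!/usr/bin/env python
"""Render validation-experiment panels from the tidy TSVs.

Reads the outputs of ``sweepabc validate`` (or the functions in
``sweepabc.validation``) and draws the standard panels: model-posterior
boxplots across a scenario series, power heatmaps over (alpha, f1),
calibration bars with the 10^c/(1+10^c) expectation, and averaged posterior
curves from a parameter-recovery JSON.

Usage:
    python scripts/plot_validation.py power power.tsv out_power.png
    python scripts/plot_validation.py calibration calib.bins.tsv out_calib.png
    python scripts/plot_validation.py recovery recovery.json out_recovery.png
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

MODEL_COLORS = {"NT": "#7f7f7f", "SSV": "#ff7f0e", "SDN": "#1f77b4"}


def plot_power(tsv: Path, out: Path) -> None:
    import matplotlib.pyplot as plt

    df = pd.read_csv(tsv, sep="\t")
    cells = df.groupby(["truth", "alpha", "f1", "f_cur"], dropna=False)
    labels, series = [], {m: [] for m in ("NT", "SSV", "SDN")}
    for key, g in cells:
        truth, alpha, f1, f_cur = key
        labels.append(f"{truth}\na={alpha:g}" + ("" if pd.isna(f1) else f"\nf1={f1:g}"))
        for m in series:
            series[m].append(g[f"pr_{m}"].to_numpy())
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    width = 0.25
    for k, (m, vals) in enumerate(series.items()):
        pos = np.arange(len(labels)) + (k - 1) * width
        bp = ax.boxplot(vals, positions=pos, widths=width * 0.9, whis=(2.5, 97.5),
                        patch_artist=True, showfliers=False)
        for box in bp["boxes"]:
            box.set_facecolor(MODEL_COLORS[m])
    ax.set_xticks(np.arange(len(labels)))
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("posterior probability")
    ax.set_ylim(0, 1)
    handles = [plt.Rectangle((0, 0), 1, 1, fc=c) for c in MODEL_COLORS.values()]
    ax.legend(handles, MODEL_COLORS.keys(), loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)


def plot_calibration(tsv: Path, out: Path) -> None:
    import matplotlib.pyplot as plt

    df = pd.read_csv(tsv, sep="\t")
    df = df[df["count"] > 0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(df["bin_center"], df["observed_ssv_fraction"], width=0.4,
           color="#bbbbbb", edgecolor="k", label="observed")
    c = np.linspace(df["bin_center"].min() - 0.3, df["bin_center"].max() + 0.3, 200)
    ax.plot(c, 10.0**c / (1 + 10.0**c), "r-", label=r"$10^c/(1+10^c)$")
    for _, row in df[df["flagged"]].iterrows():
        ax.plot(row["bin_center"], row["observed_ssv_fraction"], "rx", ms=12)
    ax.set_xlabel(r"$\log_{10}$ Bayes factor (SSV/SDN)")
    ax.set_ylabel("fraction of SSV-truth datasets")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=150)


def plot_recovery(js: Path, out: Path) -> None:
    import matplotlib.pyplot as plt

    data = json.loads(Path(js).read_text())
    params = list(data)
    fig, axes = plt.subplots(1, len(params), figsize=(3.2 * len(params), 3.2))
    if len(params) == 1:
        axes = [axes]
    for ax, name in zip(axes, params):
        d = data[name]
        grid = np.asarray(d["grid"])
        dens = np.asarray(d["mean_density"])
        ax.plot(grid, dens / np.trapezoid(dens, grid), color="#1f77b4",
                label="avg posterior")
        ax.axhline(1.0 / (grid[-1] - grid[0]), color="0.6", ls="--", label="prior")
        if "true" in d:
            ax.axvline(d["true"], color="r", ls=":", label="truth")
        ax.set_title(name, fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)


def main(argv: list[str]) -> int:
    if len(argv) != 4 or argv[1] not in ("power", "calibration", "recovery"):
        print(__doc__, file=sys.stderr)
        return 2
    kind, src, out = argv[1], Path(argv[2]), Path(argv[3])
    {"power": plot_power, "calibration": plot_calibration,
     "recovery": plot_recovery}[kind](src, out)
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv))
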