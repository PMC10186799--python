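"""Minimal figure output: F_ST heatmap, PCoA scatter, unique-gene bars."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .genecontent import UniqueGeneReport
from .popstruct import FstResult, PCoAResult


def fst_heatmap(result: FstResult, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    m = result.fst.to_numpy()
    im = ax.imshow(m, cmap="viridis", vmin=min(0, m.min()), vmax=max(1, m.max()))
    ax.set_xticks(range(len(result.labels)), result.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(result.labels)), result.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="$F_{ST}$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pcoa_scatter(
    result: PCoAResult,
    path,
    hue: Optional[Mapping[str, str]] = None,
    axes: Sequence[str] = ("PC1", "PC2"),
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    x, y = axes[0], axes[1] if axes[1] in coords.columns else None
    groups = {}
    for sample in coords.index:
        groups.setdefault(hue.get(sample, "sample") if hue else "sample", []).append(sample)
    for label, members in groups.items():
        xs = coords.loc[members, x]
        ys = coords.loc[members, y] if y else np.zeros(len(members))
        ax.scatter(xs, ys, label=label, s=30)
    prop = result.proportion_explained
    ax.set_xlabel(f"{x} ({prop[0] * 100:.1f}%)" if len(prop) > 0 else x)
    if y:
        ax.set_ylabel(f"{y} ({prop[1] * 100:.1f}%)" if len(prop) > 1 else y)
    if hue:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def unique_gene_bars(report: UniqueGeneReport, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if report.category_counts is not None and not report.category_counts.empty:
        report.category_counts.plot.barh(stacked=True, ax=ax)
        ax.set_xlabel("unique gene clusters")
    else:
        groups = list(report.unique)
        ax.barh(groups, [len(report.unique[g]) for g in groups])
        ax.set_xlabel("unique gene clusters")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
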