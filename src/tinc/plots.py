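"""Diagnostic plots: tumour/normal VAF scatter and deconvolution histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_model import SNVRecord
from .pipeline_classify import TincResult


def plot_vaf_scatter(result: TincResult, path: str | Path) -> None:
    """Tumour vs normal VAF, clonal mutations highlighted."""
    snvs = result.used_snvs
    t = np.array([s.t_vaf for s in snvs])
    n = np.array([s.n_vaf for s in snvs])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t, n, s=8, c="lightgrey", label="all SNVs")
    if result.selection is not None and len(result.selection) > 0:
        idx = result.selection.snv_indices
        ax.scatter(t[idx], n[idx], s=10, c="teal", label="clonal")
    ax.set_xlabel("tumour VAF")
    ax.set_ylabel("normal VAF")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vaf_histograms(result: TincResult, path: str | Path) -> None:
    """Stacked tumour and normal VAF histograms with fitted summaries."""
    snvs = result.used_snvs
    t = np.array([s.t_vaf for s in snvs])
    n = np.array([s.n_vaf for s in snvs])
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    axes[0].hist(t, bins=60, color="indianred")
    axes[0].set_ylabel("tumour SNVs")
    if result.mobster is not None:
        for mean, _ in result.mobster.betas:
            axes[0].axvline(mean, color="black", ls="--", lw=1)
    axes[1].hist(n, bins=60, color="steelblue")
    axes[1].set_ylabel("normal SNVs")
    axes[1].set_xlabel("VAF")
    if result.bmix is not None:
        for p in result.bmix.p:
            axes[1].axvline(p, color="black", ls="--", lw=1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
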