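"""Plot helpers mirroring the standard figures of a cleavage analysis."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .annotation import TranscriptModel
from .metrics import MetageneProfile


def te_scatter(
    classification: pd.DataFrame,
    te_fold_gate: float = 2.0,
    mito_mask: Optional[pd.Series] = None,
    ax=None,
):
    """RNA vs ribo log2 fold-change scatter with TE-change diagonals.

    Considered genes are colored by category; the dotted diagonals mark
    ``|delta_log2_te| = log2(te_fold_gate)``.  ``mito_mask`` highlights
    mitochondrially encoded genes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = classification[classification["category"] != "filtered_out"]
    colors = {"te_up": "tab:red", "te_down": "tab:blue", "no_te_change": "0.4"}
    for cat, c in colors.items():
        s = sub[sub["category"] == cat]
        ax.scatter(s["log2fc_rna"], s["log2fc_ribo"], s=12, c=c, label=cat, alpha=0.8)
    if mito_mask is not None:
        m = sub.index.intersection(mito_mask.index[mito_mask])
        ax.scatter(sub.loc[m, "log2fc_rna"], sub.loc[m, "log2fc_ribo"],
                   s=24, facecolors="none", edgecolors="orange", label="mitochondrial")
    lims = ax.get_xlim()
    x = np.linspace(*lims, 10)
    g = np.log2(te_fold_gate)
    ax.plot(x, x, "k-", lw=0.8)
    ax.plot(x, x + g, "k:", lw=0.8)
    ax.plot(x, x - g, "k:", lw=0.8)
    ax.set_xlabel("RNA-seq log2 fold change")
    ax.set_ylabel("Ribo CDS log2 fold change")
    ax.legend(frameon=False, fontsize=8)
    return ax


def metagene_plot(profiles: dict, ax=None):
    """Overlay metagene profiles (label -> MetageneProfile)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for label, prof in profiles.items():
        ax.plot(prof.offsets, prof.mean_normalized_occupancy, label=label, lw=1)
    ax.axvline(0, color="k", lw=0.6, ls="--")
    ax.set_xlabel("offset from anchor P-site (nt)")
    ax.set_ylabel("mean normalized occupancy")
    ax.legend(frameon=False, fontsize=8)
    return ax


def gene_track(
    track: np.ndarray,
    model: TranscriptModel,
    called_uorf_starts: Sequence[int] = (),
    ax=None,
):
    """Per-gene P-site track with start-codon markers (green = uORF starts,
    red = main start)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    ax.bar(np.arange(model.length), track, width=1.0, color="0.3")
    ax.axvline(model.cds_start, color="red", lw=1, label="main start")
    ax.axvline(model.cds_end, color="0.6", lw=0.8)
    for s in called_uorf_starts:
        ax.axvline(s, color="green", lw=1)
    ax.set_xlabel(f"{model.transcript_id} position (nt)")
    ax.set_ylabel("P-sites")
    return ax
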