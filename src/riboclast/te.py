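"""Translation efficiency: per-replicate TE and TE-change classification.

TE is the CDS ribosome-footprint rpm divided by the CDS RNA-seq rpm of the
matched sample — a proxy for ribosome loading per transcript.  TE *changes*
between conditions are classified from the two assays' differential results:
delta_log2_te = log2fc(ribo) - log2fc(rna), after a filter cascade that
keeps only strongly and significantly changing, well-expressed genes
(|log2fc| > 4 in either assay with padj < 0.01, normalized mean counts > 50
in both).  A gene is te_up/te_down when |delta_log2_te| exceeds log2 of the
TE fold gate (default 2-fold, the dotted diagonals of a ribo-vs-RNA
fold-change scatter).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LFC_GATE = 4.0
DEFAULT_PADJ_GATE = 0.01
DEFAULT_BASEMEAN_GATE = 50.0
DEFAULT_TE_FOLD_GATE = 2.0

DEFAULT_MITO_PREFIXES = ("MT-",)

CATEGORIES = ("te_up", "te_down", "no_te_change", "filtered_out")


def compute_te(
    ribo_cds_rpm: pd.DataFrame,
    rna_cds_rpm: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene, per-sample TE = ribo CDS rpm / RNA CDS rpm.

    The two matrices must share the same sample columns (matched replicate
    structure).  Samples where the RNA rpm is zero give NaN (undefined TE,
    excluded from downstream means and logged); ribo 0 over RNA > 0 is a
    genuine TE of 0.
    """
    if list(ribo_cds_rpm.columns) != list(rna_cds_rpm.columns):
        raise ValueError(
            "ribo and rna matrices must have identical sample columns "
            f"({list(ribo_cds_rpm.columns)} vs {list(rna_cds_rpm.columns)})"
        )
    common = ribo_cds_rpm.index.intersection(rna_cds_rpm.index)
    ribo = ribo_cds_rpm.loc[common]
    rna = rna_cds_rpm.loc[common]
    te = ribo / rna.where(rna > 0)
    n_undef = int(te.isna().sum().sum())
    if n_undef:
        logger.info("compute_te: %d gene/sample TE values undefined (rna rpm 0)", n_undef)
    return te


def classify_te_changes(
    de_ribo: pd.DataFrame,
    de_rna: pd.DataFrame,
    lfc_gate: float = DEFAULT_LFC_GATE,
    padj_gate: float = DEFAULT_PADJ_GATE,
    basemean_gate: float = DEFAULT_BASEMEAN_GATE,
    te_fold_gate: float = DEFAULT_TE_FOLD_GATE,
) -> pd.DataFrame:
    """Classify per-gene TE changes from matched ribo and RNA DE tables.

    A gene is considered iff it passes, in order,
    (1) |log2fc| > lfc_gate with padj < padj_gate in the ribo OR the rna
    assay, and (2) base_mean > basemean_gate in BOTH assays.  Considered
    genes are te_up when delta_log2_te > log2(te_fold_gate), te_down when
    below -log2(te_fold_gate), else no_te_change.  Removed genes carry the
    name of the gate that removed them in ``filter_trace``.
    """
    common = de_ribo.index.intersection(de_rna.index)
    ribo = de_ribo.loc[common]
    rna = de_rna.loc[common]
    delta = ribo["log2fc"] - rna["log2fc"]
    sig_ribo = (ribo["log2fc"].abs() > lfc_gate) & (ribo["padj"] < padj_gate)
    sig_rna = (rna["log2fc"].abs() > lfc_gate) & (rna["padj"] < padj_gate)
    pass_lfc = sig_ribo | sig_rna
    pass_bm = (ribo["base_mean"] > basemean_gate) & (rna["base_mean"] > basemean_gate)

    log2_gate = np.log2(te_fold_gate)
    category = np.full(len(common), "no_te_change", dtype=object)
    category[(delta > log2_gate).to_numpy()] = "te_up"
    category[(delta < -log2_gate).to_numpy()] = "te_down"
    trace = np.full(len(common), "", dtype=object)
    trace[~pass_bm.to_numpy()] = "basemean_gate"
    trace[~pass_lfc.to_numpy()] = "lfc_padj_gate"  # first gate wins the trace
    considered = (pass_lfc & pass_bm).to_numpy()
    category[~considered] = "filtered_out"

    return pd.DataFrame(
        {
            "log2fc_rna": rna["log2fc"],
            "log2fc_ribo": ribo["log2fc"],
            "delta_log2_te": delta,
            "category": category,
            "filter_trace": trace,
        },
        index=pd.Index(common, name="gene_id"),
    )


def tag_mitochondrial(
    genes: Iterable[str],
    prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
) -> pd.Series:
    """Boolean mask of mitochondrially encoded genes by name prefix."""
    genes = list(genes)
    return pd.Series(
        [any(g.startswith(p) for p in prefixes) for g in genes],
        index=pd.Index(genes, name="gene_id"),
        name="mitochondrial",
    )
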