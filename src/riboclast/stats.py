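"""Count normalization and differential-expression statistics.

Normalization uses median-of-ratios size factors.  The differential test is
a deliberately simple, fully documented pipeline: log2(normalized + 0.5)
per replicate, a two-sided t-test between groups (pooled variance by
default, Welch optional), and Benjamini-Hochberg adjustment.  This trades the negative-binomial machinery
of dedicated DE packages for transparency and speed on deep, replicated
count tables; externally produced DE tables (gene, log2fc, pvalue, padj)
can be imported for full fidelity.

Note that on a globally degraded transcriptome these statistics are
relative: a positive log2 fold change means a transcript lost less than the
general population (or was transcriptionally compensated), not that its
absolute copy number rose.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["base_mean", "log2fc", "pvalue", "padj", "flag_de"]

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For every gene with nonzero counts in all samples, compute the ratio of
    each sample's count to the gene's geometric mean; the factor is the
    per-sample median of these ratios.  Deterministic; raises if no gene is
    nonzero everywhere (a pseudo-reference fallback would be needed for such
    sparse matrices).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference (mean-count) fallback"
        )
    sub = mat[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with degenerate handling:
    zero variance in both groups gives p=1 for equal means, p=0 otherwise."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a[degenerate].mean(axis=1), b[degenerate].mean(axis=1))
        p[degenerate] = np.where(equal, 1.0, 0.0)
    return p


def differential_expression(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    control_label: str,
    treated_label: str,
    pseudocount: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene differential expression, treated vs control.

    Counts are normalized by median-of-ratios size factors (over the samples
    in the two groups), shifted by ``pseudocount`` and log2-transformed;
    ``log2fc`` is the treated-minus-control mean difference of these values
    and the p-value comes from a two-sided t-test across replicates.  The
    default pooled-variance (Student) test is exactly calibrated for
    exchangeable equal-size groups, which matters at the 2-3 replicates
    typical of these designs (the Welch/Satterthwaite approximation is
    measurably conservative there); set ``equal_var=False`` for Welch when
    group variances may differ.
    ``flag_de`` marks genes with padj < alpha and |log2fc| > lfc_threshold.
    Returns a gene-indexed frame with base_mean (mean normalized count over
    all samples used), log2fc, pvalue, padj, flag_de.
    """
    ctrl = [s for s in counts.columns if conditions[s] == control_label]
    trt = [s for s in counts.columns if conditions[s] == treated_label]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(
            f"need >= 2 replicates per group (control={len(ctrl)}, treated={len(trt)})"
        )
    sub = counts[ctrl + trt]
    sf = size_factors(sub)
    norm = sub / sf
    logn = np.log2(norm + pseudocount)
    a = logn[trt].to_numpy()
    b = logn[ctrl].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    pvalue = _log_t(a, b, equal_var)
    padj = bh_adjust(pvalue)
    out = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.index.rename("gene_id"),
    )
    out["flag_de"] = (out["padj"] < alpha) & (out["log2fc"].abs() > lfc_threshold)
    return out


def import_external_de(path: str) -> pd.DataFrame:
    """Import an externally produced DE table (TSV with columns gene_id,
    log2fc, pvalue, padj; optional base_mean), e.g. from a dedicated
    negative-binomial DE package run by the user."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external DE table lacks columns {sorted(missing)}")
    df = df.set_index("gene_id")
    if "base_mean" not in df.columns:
        df["base_mean"] = np.nan
    df["flag_de"] = (df["padj"] < DEFAULT_ALPHA) & (
        df["log2fc"].abs() > DEFAULT_LFC_THRESHOLD
    )
    return df


@dataclass
class GeneSetSummary:
    """Per-contrast log2fc values for a gene set plus paired tests."""

    log2fc: Dict[str, pd.Series]
    paired_tests: pd.DataFrame


def geneset_summary(
    de_tables: Mapping[str, pd.DataFrame],
    gene_set: Iterable[str],
    min_genes: int = 3,
) -> GeneSetSummary:
    """Restrict each contrast's log2fc to a gene set and pair-test contrasts.

    Returns the per-gene log2fc vectors (violin-plot data) and, for every
    pair of contrasts, a two-sided paired t-test over genes present in both.
    Pairs whose per-gene differences have zero variance are flagged
    degenerate and get no p-value.
    """
    if len(de_tables) < 2:
        raise ValueError("need at least two contrasts")
    genes = list(dict.fromkeys(gene_set))
    vectors: Dict[str, pd.Series] = {}
    for name, de in de_tables.items():
        present = [g for g in genes if g in de.index]
        if len(present) < min_genes:
            raise ValueError(
                f"contrast {name!r}: only {len(present)} gene-set genes measured "
                f"(need >= {min_genes})"
            )
        vectors[name] = de.loc[present, "log2fc"]
    rows = []
    for a, b in combinations(vectors, 2):
        common = vectors[a].index.intersection(vectors[b].index)
        if len(common) < min_genes:
            raise ValueError(f"contrast pair ({a}, {b}): fewer than {min_genes} paired genes")
        diff = (vectors[a].loc[common] - vectors[b].loc[common]).to_numpy()
        degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
        if degenerate:
            pval = np.nan
        else:
            pval = float(sps.ttest_rel(vectors[a].loc[common], vectors[b].loc[common]).pvalue)
        rows.append(
            {
                "contrast_a": a,
                "contrast_b": b,
                "n_pairs": len(common),
                "mean_difference": float(diff.mean()),
                "pvalue": pval,
                "degenerate": degenerate,
            }
        )
    return GeneSetSummary(vectors, pd.DataFrame(rows))


def correlate_changes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    selection: str = "de_in_A",
) -> Tuple[float, float, int]:
    """Pearson correlation of paired log2fc values for a gene subset.

    ``selection`` mirrors sequential DE filtering between two contrasts:
    ``de_in_A`` / ``de_in_B`` keep genes flagged DE in that contrast,
    ``de_in_either`` their union, and ``below_threshold_in_A`` the genes NOT
    flagged DE in A (the sub-threshold changes).  Returns (r, r^2, n_genes).
    """
    common = de_a.index.intersection(de_b.index)
    a = de_a.loc[common]
    b = de_b.loc[common]
    if selection == "de_in_A":
        mask = a["flag_de"]
    elif selection == "de_in_B":
        mask = b["flag_de"]
    elif selection == "de_in_either":
        mask = a["flag_de"] | b["flag_de"]
    elif selection == "below_threshold_in_A":
        mask = ~a["flag_de"]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    x = a.loc[mask, "log2fc"].to_numpy()
    y = b.loc[mask, "log2fc"].to_numpy()
    if x.size < 3:
        raise ValueError(f"selection {selection!r} keeps only {x.size} genes (need >= 3)")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r, int(x.size)


def load_gene_set(path: str) -> List[str]:
    """Read a one-column gene list (TSV/plain text, optional header
    'gene_id', comment lines starting with #)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip().split("\t")[0]
            if not tok or tok.startswith("#") or tok == "gene_id":
                continue
            genes.append(tok)
    return genes
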