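"""altORF translation statistics: UTR:ORF ratios and metagene profiles.

The headline signature of translation on endonucleolytic cleavage fragments
is a rise in the fraction of ribosome footprints found outside the main ORF.
Two summaries quantify it: the ratio of UTR to CDS footprint rpm (per gene,
or aggregated over the expressed transcriptome), and the normalized average
occupancy around start/stop codons (metagene profile), where fragment
re-initiation appears as elevated occupancy downstream of the stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptomeSet
from .psites import PSiteTrackSet, RegionCountMatrix


def utr_orf_ratio(
    rpm: RegionCountMatrix,
    which: str = "utr3",
    scope: str = "aggregate",
    min_cds_rpm: float = 1.0,
) -> pd.DataFrame:
    """UTR:ORF footprint ratios per sample.

    ``which`` selects the numerator region (``utr3`` or ``utr5``); the
    denominator is always the CDS.  Genes must reach ``min_cds_rpm`` CDS rpm
    in a sample to be used (guards the per-gene division and drops barely
    expressed genes).  ``scope="per_gene"`` returns one row per passing gene
    and sample; ``scope="aggregate"`` returns one row per sample with
    ratio = sum(utr rpm) / sum(cds rpm) over the same passing gene set.
    """
    if which not in ("utr3", "utr5"):
        raise ValueError(f"which must be utr3 or utr5, got {which!r}")
    if scope not in ("aggregate", "per_gene"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "per_gene" and min_cds_rpm <= 0:
        raise ValueError("per_gene scope requires min_cds_rpm > 0")
    utr = rpm[which]
    cds = rpm["cds"]
    rows = []
    for sample in rpm.samples:
        passing = cds[sample] >= min_cds_rpm
        n = int(passing.sum())
        if scope == "aggregate":
            denom = float(cds.loc[passing, sample].sum())
            ratio = float(utr.loc[passing, sample].sum()) / denom if denom > 0 else np.nan
            rows.append(
                {"sample_id": sample, "scope": scope, "gene_id": None,
                 "which": which, "ratio": ratio, "genes_used": n}
            )
        else:
            sub = (utr.loc[passing, sample] / cds.loc[passing, sample])
            for gene, r in sub.items():
                rows.append(
                    {"sample_id": sample, "scope": scope, "gene_id": gene,
                     "which": which, "ratio": float(r), "genes_used": n}
                )
    return pd.DataFrame(rows)


@dataclass
class MetageneProfile:
    """Mean normalized P-site occupancy around an anchor codon.

    ``offsets[i]`` is the position relative to the anchor P-site (0 = the
    first CDS codon for ``start_codon`` anchors, the stop codon itself for
    ``stop_codon`` anchors); ``mean_normalized_occupancy[i]`` is the average
    over genes of per-position counts divided by each gene's mean CDS
    density, so a uniformly translated transcriptome gives a flat profile
    at 1.
    """

    anchor: str
    offsets: np.ndarray
    mean_normalized_occupancy: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_normalized_occupancy": self.mean_normalized_occupancy,
                "n_genes": self.n_genes,
            }
        )

    def mean_over(self, lo: int, hi: int) -> float:
        """Mean profile value over offsets in [lo, hi)."""
        sel = (self.offsets >= lo) & (self.offsets < hi)
        return float(self.mean_normalized_occupancy[sel].mean())


def metagene(
    tracks: PSiteTrackSet,
    transcriptome: TranscriptomeSet,
    anchor: str = "stop_codon",
    window: Tuple[int, int] = (60, 90),
    min_cds_density: float = 0.5,
) -> MetageneProfile:
    """Average normalized occupancy around start or stop codons.

    ``window = (upstream_nt, downstream_nt)`` spans offsets
    ``[-upstream, +downstream]`` inclusive around the anchor P-site.  Genes
    qualify when their mean CDS P-site density reaches ``min_cds_density``
    (reads/nt) and the whole window lies inside the transcript (windows that
    would cross a transcript edge are excluded, not zero-padded).  Each
    qualifying gene's window vector is divided by its mean CDS density; the
    profile is the equal-weight average of these vectors.
    """
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"anchor must be start_codon or stop_codon, got {anchor!r}")
    up, down = window
    offsets = np.arange(-up, down + 1)
    acc = np.zeros(offsets.size)
    n = 0
    for tid, track in tracks:
        model = transcriptome[tid]
        cds_len = model.cds_end - model.cds_start
        if cds_len <= 0:
            continue
        dens = float(track[model.cds_start : model.cds_end].sum()) / cds_len
        if dens < min_cds_density:
            continue
        a = model.cds_start if anchor == "start_codon" else model.cds_end - 3
        lo, hi = a - up, a + down + 1
        if lo < 0 or hi > model.length:
            continue
        acc += track[lo:hi] / dens
        n += 1
    if n == 0:
        raise ValueError("empty metagene: no gene passes min_cds_density with a full window")
    return MetageneProfile(anchor, offsets, acc / n, n)
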