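"""uORF translation detection and 5'UTR:main-ORF shift quantification.

uORF translation shows up as P-site peaks at AUG or near-cognate (CUG/GUG)
start codons in the 5'UTR; the balance between uORF and main-ORF initiation
shifts when eIF2alpha is phosphorylated (the ISR regime of ATF4/GADD34/CHOP
and the IFIT genes).  The shift is quantified per gene as the ratio of
5'UTR to main-ORF footprint rpm, compared between conditions on the log2
scale with a per-replicate Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import (
    DEFAULT_START_CODONS,
    TranscriptModel,
    UORFAnnotation,
    scan_orfs,
)
from .psites import RegionCountMatrix

logger = logging.getLogger(__name__)

#: half-width of the start-codon peak window, in nt: the start codon plus
#: one codon on each side (window width 9).
PEAK_FLANK = 3


@dataclass
class UORFSignal:
    """Peak evidence for one candidate uORF start."""

    gene_id: str
    uorf: UORFAnnotation
    start_peak_count: float
    local_background: float
    peak_score: float
    called: bool


def detect_uorf_peaks(
    track: np.ndarray,
    model: TranscriptModel,
    sequence: str,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    score_threshold: float = 5.0,
    min_reads: float = 10.0,
    min_codons: int = 2,
) -> List[UORFSignal]:
    """Score candidate uORF starts in the 5'UTR of one transcript.

    Candidates come from an ORF scan of the 5'UTR sequence.  Each start is
    scored by the P-site count in its start codon +/- 1 codon against the
    mean 5'UTR density computed outside all candidate peak windows
    (peak_score = peak count / (background * window width)); a uORF is
    called when the score reaches ``score_threshold`` and the peak holds at
    least ``min_reads``.  Transcripts whose 5'UTR is shorter than the peak
    window are skipped with a log entry.  Signals are sorted by score.
    """
    utr_len = model.cds_start
    window_width = 2 * PEAK_FLANK + 3
    if utr_len < window_width:
        logger.info(
            "detect_uorf_peaks: %s skipped (5'UTR %d nt < window %d nt)",
            model.transcript_id, utr_len, window_width,
        )
        return []
    utr_seq = sequence[:utr_len]
    candidates = scan_orfs(utr_seq, start_codons, min_codons=min_codons)
    if not candidates:
        return []
    utr_track = np.asarray(track[:utr_len], dtype=float)
    peak_mask = np.zeros(utr_len, dtype=bool)
    windows = []
    for c in candidates:
        lo = max(c.start - PEAK_FLANK, 0)
        hi = min(c.start + 3 + PEAK_FLANK, utr_len)
        windows.append((lo, hi))
        peak_mask[lo:hi] = True
    outside = utr_track[~peak_mask]
    background = float(outside.mean()) if outside.size else 0.0

    signals = []
    for c, (lo, hi) in zip(candidates, windows):
        peak = float(utr_track[lo:hi].sum())
        if background > 0:
            score = peak / (background * window_width)
        else:
            score = np.inf if peak > 0 else 0.0
        called = bool(score >= score_threshold and peak >= min_reads)
        # candidate ORFs may run past the 5'UTR (ATF4-style overlap) or be
        # open-ended at the UTR scan boundary; annotate as scanned
        signals.append(
            UORFSignal(
                gene_id=model.gene_id,
                uorf=UORFAnnotation(c.start, c.end, c.start_codon),
                start_peak_count=peak,
                local_background=background,
                peak_score=score,
                called=called,
            )
        )
    signals.sort(key=lambda s: s.peak_score, reverse=True)
    return signals


def uorf_signals_frame(signals: Iterable[UORFSignal]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "uorf_start": s.uorf.start,
            "uorf_end": s.uorf.end,
            "start_codon": s.uorf.start_codon,
            "start_peak_count": s.start_peak_count,
            "local_background": s.local_background,
            "peak_score": s.peak_score,
            "called": s.called,
        }
        for s in signals
    ]
    return pd.DataFrame(rows)


@dataclass
class ShiftResult:
    """5'UTR:main-ORF translation shift for one gene between conditions."""

    gene_id: str
    ratio_per_sample: pd.Series  # utr5 rpm / cds rpm, indexed by sample
    log2_shift: float  # log2(mean treated ratio / mean control ratio)
    p_value: float


def utr5_main_shift(
    rpm: RegionCountMatrix,
    gene: str,
    control_samples: Sequence[str],
    treated_samples: Sequence[str],
) -> Optional[ShiftResult]:
    """Quantify the 5'UTR:main-ORF footprint shift for one gene.

    ``rpm`` must be region rpm computed under the desired uORF-overlap
    policy (overlap positions are assigned at region-counting time; the
    default policy credits uORF/CDS overlap to the UTR).  The ratio uses
    whole-5'UTR counts.  Genes with zero CDS rpm in any sample considered
    are excluded (returns None, logged).  The p-value is a two-sided Welch
    t-test on per-replicate log2 ratios, NaN when any ratio is zero.
    """
    samples = list(control_samples) + list(treated_samples)
    cds = rpm["cds"].loc[gene, samples]
    if (cds <= 0).any():
        logger.info("utr5_main_shift: %s excluded (zero CDS rpm in a sample)", gene)
        return None
    utr5 = rpm["utr5"].loc[gene, samples]
    ratio = utr5 / cds
    ctrl = ratio[list(control_samples)].to_numpy(dtype=float)
    trt = ratio[list(treated_samples)].to_numpy(dtype=float)
    if ctrl.mean() > 0 and trt.mean() > 0:
        log2_shift = float(np.log2(trt.mean() / ctrl.mean()))
    elif trt.mean() == ctrl.mean():
        log2_shift = 0.0
    else:
        log2_shift = float(np.inf if trt.mean() > ctrl.mean() else -np.inf)
    if (ctrl > 0).all() and (trt > 0).all() and len(ctrl) > 1 and len(trt) > 1:
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Precision loss occurred")
            p = float(
                sps.ttest_ind(np.log2(trt), np.log2(ctrl), equal_var=False).pvalue
            )
    else:
        p = np.nan
    return ShiftResult(gene, ratio, log2_shift, p)


def shift_results_frame(results: Iterable[Optional[ShiftResult]]) -> pd.DataFrame:
    rows = [
        {"gene_id": r.gene_id, "log2_shift": r.log2_shift, "p_value": r.p_value}
        for r in results
        if r is not None
    ]
    return pd.DataFrame(rows)
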