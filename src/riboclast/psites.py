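"""Footprint alignments, P-site tracks, and region counting.

A ribosome footprint aligned in transcript space is reduced to a single
P-site position: the 5' end of the read plus a fixed offset (12 nt by
default, applied globally to all read lengths).  Per-transcript P-site
count vectors are then summed over the annotated 5'UTR / CDS / 3'UTR
intervals (plus a uORF layer) to give gene x sample region counts, the
numerators and denominators of every downstream UTR:ORF statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, TranscriptomeSet

logger = logging.getLogger(__name__)

DEFAULT_PSITE_OFFSET = 12
REGIONS = ("utr5", "cds", "utr3", "uorf")

ALIGNMENT_COLUMNS = ["transcript_id", "five_prime", "read_length", "weight"]


@dataclass(frozen=True)
class FootprintAlignment:
    """One footprint: 5'-end transcript coordinate plus length and weight.

    ``weight`` defaults to 1 and may be fractional for multimappers; weights
    are taken as given, no re-resolution is attempted.
    """

    transcript_id: str
    five_prime: int
    read_length: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError("five_prime must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def alignments_frame(alignments) -> pd.DataFrame:
    """Coerce an iterable of FootprintAlignment or a DataFrame to the
    canonical alignment frame (transcript_id, five_prime, read_length,
    weight)."""
    if isinstance(alignments, pd.DataFrame):
        df = alignments.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"alignment frame lacks columns {missing}")
        return df[ALIGNMENT_COLUMNS]
    rows = [
        (a.transcript_id, a.five_prime, a.read_length, a.weight)
        for a in alignments
    ]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def read_bed(path: str) -> pd.DataFrame:
    """Read transcript-space BED6 footprint records (5'-aligned, + strand:
    the BED start is the read 5' end)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["transcript_id", "start", "end", "read_id", "score", "strand"],
        dtype={"transcript_id": str},
    )
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "five_prime": df["start"].astype(int),
            "read_length": (df["end"] - df["start"]).astype(int),
            "weight": pd.to_numeric(df["score"], errors="coerce").fillna(1.0),
        }
    )
    return out


def read_sam(path: str) -> pd.DataFrame:
    """Read footprints from a SAM/BAM aligned against the transcript FASTA.

    Reads are taken as 5'-aligned: the reference start of a forward-strand
    alignment is the footprint 5' end.  Reverse-strand and unmapped records
    are skipped.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_reverse:
                continue
            rows.append(
                (rec.reference_name, rec.reference_start, rec.query_length or rec.infer_read_length())
            )
    df = pd.DataFrame(rows, columns=["transcript_id", "five_prime", "read_length"])
    df["weight"] = 1.0
    return df


def load_footprints(path: str) -> pd.DataFrame:
    """Load footprint alignments from BED6 (.bed) or SAM/BAM (.sam/.bam)."""
    if path.endswith((".sam", ".bam")):
        return read_sam(path)
    return read_bed(path)


class PSiteTrackSet:
    """Per-transcript P-site count vectors for one sample.

    ``tracks[tid]`` is a float vector of length equal to the transcript;
    ``discarded`` tallies alignment weight whose shifted P-site fell off the
    transcript 3' end (dropped, never clamped).
    """

    def __init__(self, sample_id: str, tracks: Dict[str, np.ndarray], discarded: float = 0.0):
        self.sample_id = sample_id
        self.tracks = tracks
        self.discarded = discarded

    def __getitem__(self, transcript_id: str) -> np.ndarray:
        return self.tracks[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.tracks

    def __iter__(self):
        return iter(self.tracks.items())

    @property
    def total(self) -> float:
        return float(sum(t.sum() for t in self.tracks.values()))


def assign_psites(
    alignments,
    transcriptome: TranscriptomeSet,
    offset: int = DEFAULT_PSITE_OFFSET,
    sample_id: str = "sample",
) -> PSiteTrackSet:
    """Build P-site tracks: each alignment adds its weight at
    ``five_prime + offset``.

    Positions shifted past the transcript end are discarded and counted in
    the track set's discard tally.  Unannotated transcripts raise.
    """
    if offset < 0:
        raise ValueError("P-site offset must be non-negative")
    df = alignments_frame(alignments)

    unknown = set(df["transcript_id"].unique()) - set(transcriptome.models)
    if unknown:
        raise ValueError(
            f"alignments reference unannotated transcripts: {sorted(unknown)[:5]}"
        )

    tids = list(transcriptome.models)
    lengths = np.array([transcriptome[t].length for t in tids], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    index = {t: i for i, t in enumerate(tids)}

    tx_idx = df["transcript_id"].map(index).to_numpy(dtype=np.int64)
    psite = df["five_prime"].to_numpy(dtype=np.int64) + offset
    weight = df["weight"].to_numpy(dtype=float)
    if (df["five_prime"].to_numpy() < 0).any():
        raise ValueError("negative five_prime coordinate in alignments")

    keep = psite < lengths[tx_idx]
    discarded = float(weight[~keep].sum())
    flat = offsets[tx_idx[keep]] + psite[keep]
    counts = np.bincount(flat, weights=weight[keep], minlength=int(offsets[-1]))

    tracks = {
        t: counts[offsets[i] : offsets[i + 1]].astype(float)
        for t, i in index.items()
    }
    if discarded:
        logger.info("assign_psites[%s]: discarded weight %.3f past 3' ends", sample_id, discarded)
    return PSiteTrackSet(sample_id, tracks, discarded)


@dataclass(frozen=True)
class OffsetCalibration:
    offset: int
    scores: Dict[int, float]
    low_confidence: bool


def calibrate_psite_offset(
    alignments,
    transcriptome: TranscriptomeSet,
    window: int = 3,
    candidates: Sequence[int] = range(10, 15),
    min_reads: int = 100,
) -> OffsetCalibration:
    """Recover the P-site offset from the initiation peak at start codons.

    For each candidate offset the 5'-end counts at ``cds_start - offset``
    are summed over all transcripts; the argmax wins, with ties broken
    toward 12 (flagged low-confidence).  Requires at least ``min_reads``
    read weight with 5' ends inside the start-codon windows
    ``[cds_start - max(candidates) - window, cds_start + window]``.
    """
    df = alignments_frame(alignments)
    candidates = list(candidates)
    scores = {c: 0.0 for c in candidates}
    in_window = 0.0
    lo_pad = max(candidates) + window
    by_tx = df.groupby("transcript_id", observed=True)
    for tid, sub in by_tx:
        if tid not in transcriptome:
            continue
        cs = transcriptome[tid].cds_start
        fp = sub["five_prime"].to_numpy()
        w = sub["weight"].to_numpy(dtype=float)
        sel = (fp >= cs - lo_pad) & (fp <= cs + window)
        in_window += float(w[sel].sum())
        for c in candidates:
            scores[c] += float(w[fp == cs - c].sum())
    if in_window < min_reads:
        raise ValueError(
            f"cannot calibrate: only {in_window:.0f} reads overlap start-codon "
            f"windows (need >= {min_reads})"
        )
    best = max(scores.values())
    winners = sorted(c for c, s in scores.items() if s == best)
    if DEFAULT_PSITE_OFFSET in winners:
        chosen = DEFAULT_PSITE_OFFSET
    else:
        chosen = winners[0]
    return OffsetCalibration(chosen, scores, low_confidence=len(winners) > 1)


# ---------------------------------------------------------------------------
# Region counting
# ---------------------------------------------------------------------------


class RegionCountMatrix:
    """Gene x sample counts split by region (utr5, cds, utr3, uorf).

    ``counts[region]`` is a genes x samples DataFrame; the utr5/cds/utr3
    layers tile every transcript so their per-gene sum equals the track
    total (minus discards).  The uorf layer overlaps utr5 (and possibly cds)
    and sits outside the tiling identity.  ``library_sizes`` holds each
    sample's total transcriptome-mapped P-site count, the rpm denominator.
    """

    def __init__(self, counts: Dict[str, pd.DataFrame], library_sizes: pd.Series):
        self.counts = counts
        self.library_sizes = library_sizes

    @property
    def samples(self) -> List[str]:
        return list(self.counts["cds"].columns)

    @property
    def genes(self) -> List[str]:
        return list(self.counts["cds"].index)

    def __getitem__(self, region: str) -> pd.DataFrame:
        return self.counts[region]

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for region, df in self.counts.items():
            t = df.reset_index(names="gene_id").melt(
                id_vars="gene_id", var_name="sample_id", value_name="count"
            )
            t["region"] = region
            frames.append(t)
        return pd.concat(frames, ignore_index=True)[
            ["gene_id", "sample_id", "region", "count"]
        ]

    def write_tsv(self, path: str) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)


def _region_labels(
    model: TranscriptModel, uorf_overlap_policy: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position region label (0=utr5, 1=cds, 2=utr3) and uORF mask."""
    labels = np.empty(model.length, dtype=np.int8)
    labels[: model.cds_start] = 0
    labels[model.cds_start : model.cds_end] = 1
    labels[model.cds_end :] = 2
    uorf_mask = np.zeros(model.length, dtype=bool)
    for u in model.uorfs:
        uorf_mask[u.start : u.end] = True
    if uorf_overlap_policy == "overlap_to_utr":
        labels[uorf_mask & (labels == 1)] = 0
    elif uorf_overlap_policy != "overlap_to_cds":
        raise ValueError(f"unknown uorf_overlap_policy {uorf_overlap_policy!r}")
    return labels, uorf_mask


def count_regions(
    tracksets: "PSiteTrackSet | Iterable[PSiteTrackSet]",
    transcriptome: TranscriptomeSet,
    uorf_overlap_policy: str = "overlap_to_utr",
) -> RegionCountMatrix:
    """Sum P-site tracks over each region interval, per gene and sample.

    With the default ``overlap_to_utr`` policy, positions inside a uORF that
    overlaps the CDS are credited to the 5'UTR (and to the uorf layer), not
    the CDS — the overlap rule used for ATF4-style uORFs, generalized to all
    genes.  ``overlap_to_cds`` is the complementary policy.
    """
    if isinstance(tracksets, PSiteTrackSet):
        tracksets = [tracksets]
    tracksets = list(tracksets)
    samples = [ts.sample_id for ts in tracksets]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample_ids in track sets")

    label_cache = {
        tid: _region_labels(transcriptome[tid], uorf_overlap_policy)
        for ts in tracksets
        for tid in ts.tracks
        if tid in transcriptome
    }
    genes: List[str] = []
    seen = set()
    for ts in tracksets:
        for tid in ts.tracks:
            if tid not in transcriptome:
                raise ValueError(f"track for unannotated transcript {tid!r}")
            g = transcriptome.gene_of(tid)
            if g not in seen:
                seen.add(g)
                genes.append(g)

    data = {r: np.zeros((len(genes), len(samples))) for r in REGIONS}
    gidx = {g: i for i, g in enumerate(genes)}
    lib = np.zeros(len(samples))
    for j, ts in enumerate(tracksets):
        for tid, track in ts.tracks.items():
            labels, uorf_mask = label_cache[tid]
            gi = gidx[transcriptome.gene_of(tid)]
            sums = np.bincount(labels, weights=track, minlength=3)
            data["utr5"][gi, j] += sums[0]
            data["cds"][gi, j] += sums[1]
            data["utr3"][gi, j] += sums[2]
            if uorf_mask.any():
                data["uorf"][gi, j] += float(track[uorf_mask].sum())
            lib[j] += float(track.sum())

    counts = {
        r: pd.DataFrame(data[r], index=pd.Index(genes, name="gene_id"), columns=samples)
        for r in REGIONS
    }
    return RegionCountMatrix(counts, pd.Series(lib, index=samples, name="library_size"))


def to_rpm(matrix: RegionCountMatrix) -> RegionCountMatrix:
    """Convert region counts to reads-per-million of transcriptome-mapped
    P-sites (per sample).  Zero library sizes are an error."""
    lib = matrix.library_sizes
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    rpm = {r: df * 1e6 / lib for r, df in matrix.counts.items()}
    return RegionCountMatrix(rpm, lib.copy())
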